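"""Synthetic inputs with known ground truth.

Every consumer-facing input of the toolkit can be generated here: labeled
pathogenic/neutral truth sets, per-tool prediction tables with controllable
per-region accuracy and missingness, gene-phenotype databases whose diseases
follow the panel's 19-category proportions, and simulated patients carrying
one implanted causal variant among filterable background variants.

The synthetic genome is positional only — 22 autosomes plus X as integer
intervals — because no operation in the toolkit needs nucleotide context.
All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .aadsm import DiseaseRecord, GenePhenotypeDB
from .mpps import TruthSet
from .predictors import (
    BENIGN,
    DAMAGING,
    POSSIBLY_BENIGN,
    POSSIBLY_DAMAGING,
    TOOLS,
    ToolThresholds,
    category_band_midpoint,
)
from .variants import VariantRecord

#: Approximate chromosome lengths (bp); enough structure for regional bins.
DEFAULT_GENOME: Dict[str, int] = {
    "1": 249_000_000, "2": 243_000_000, "3": 198_000_000, "4": 191_000_000,
    "5": 180_000_000, "6": 171_000_000, "7": 159_000_000, "8": 146_000_000,
    "9": 141_000_000, "10": 135_000_000, "11": 135_000_000, "12": 133_000_000,
    "13": 115_000_000, "14": 107_000_000, "15": 102_000_000, "16": 90_000_000,
    "17": 81_000_000, "18": 78_000_000, "19": 59_000_000, "20": 63_000_000,
    "21": 48_000_000, "22": 51_000_000, "X": 155_000_000,
}

_BASES = ("A", "C", "G", "T")


def _random_position(rng: np.random.Generator, genome: Mapping[str, int]) -> Tuple[str, int]:
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    c = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
    return c, int(rng.integers(1, genome[c] + 1))


def simulate_truth_set(
    n_pathogenic: int,
    n_neutral: int,
    genome: Optional[Mapping[str, int]] = None,
    seed: int = 0,
) -> Tuple[TruthSet, List[VariantRecord]]:
    """Uniformly placed labeled SNVs; deterministic per seed.

    Returns the truth map (key -> "pathogenic"/"neutral") and matching
    missense VariantRecords (the input class the ensemble scores).
    """
    if n_pathogenic < 0 or n_neutral < 0:
        raise ValueError("counts must be non-negative")
    genome = genome or DEFAULT_GENOME
    rng = np.random.default_rng(seed)
    truth: TruthSet = {}
    records: List[VariantRecord] = []
    labels = ["pathogenic"] * n_pathogenic + ["neutral"] * n_neutral
    for label in labels:
        while True:
            chrom, pos = _random_position(rng, genome)
            ref = _BASES[int(rng.integers(4))]
            alt = _BASES[int(rng.integers(4))]
            while alt == ref:
                alt = _BASES[int(rng.integers(4))]
            key = (chrom, pos, ref, alt)
            if key not in truth:
                break
        truth[key] = label
        records.append(
            VariantRecord(chrom, pos, ref, alt, "SNV", consequence="missense")
        )
    return truth, records


# ---------------------------------------------------------------------------
# Tool prediction profiles


@dataclass
class ToolAccuracySpec:
    """Per-tool (optionally per-region) generating accuracies.

    ``sensitivity``: probability a pathogenic variant is called on the
    damaging side; ``specificity``: probability a neutral variant is called
    on the benign side; ``missing_rate``: probability the tool emits nothing;
    ``possibly_rate``: fraction of calls softened to a "possibly" category.
    ``regional`` overrides (sensitivity, specificity) for a (tool, region)
    pair, region keyed as in the weight table.
    """

    sensitivity: Dict[str, float]
    specificity: Dict[str, float]
    missing_rate: Dict[str, float] = field(default_factory=dict)
    possibly_rate: Dict[str, float] = field(default_factory=dict)
    regional: Dict[Tuple[str, str], Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.sensitivity, self.specificity, self.missing_rate, self.possibly_rate):
            for tool, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"rate for {tool} outside [0,1]: {v}")

    def rates(self, tool: str, region: Optional[str]) -> Tuple[float, float, float, float]:
        sens = self.sensitivity[tool]
        spec = self.specificity[tool]
        if region is not None and (tool, region) in self.regional:
            sens, spec = self.regional[(tool, region)]
        return (
            sens,
            spec,
            self.missing_rate.get(tool, 0.0),
            self.possibly_rate.get(tool, 0.0),
        )

    @classmethod
    def uniform(
        cls,
        sensitivity: float = 0.85,
        specificity: float = 0.85,
        missing_rate: float = 0.0,
        possibly_rate: float = 0.0,
        tools: Sequence[str] = TOOLS,
    ) -> "ToolAccuracySpec":
        return cls(
            {t: sensitivity for t in tools},
            {t: specificity for t in tools},
            {t: missing_rate for t in tools},
            {t: possibly_rate for t in tools},
        )

    @classmethod
    def random(
        cls,
        seed: int,
        accuracy_range: Tuple[float, float] = (0.7, 0.95),
        missing_range: Tuple[float, float] = (0.0, 0.3),
        possibly_rate: float = 0.1,
        tools: Sequence[str] = TOOLS,
    ) -> "ToolAccuracySpec":
        rng = np.random.default_rng(seed)
        return cls(
            {t: float(rng.uniform(*accuracy_range)) for t in tools},
            {t: float(rng.uniform(*accuracy_range)) for t in tools},
            {t: float(rng.uniform(*missing_range)) for t in tools},
            {t: possibly_rate for t in tools},
        )


def simulate_tool_profiles(
    truth: TruthSet,
    records: Sequence[VariantRecord],
    spec: ToolAccuracySpec,
    seed: int = 0,
    bin_size: int = 10_000_000,
    thresholds: Optional[Mapping[str, ToolThresholds]] = None,
    tools: Sequence[str] = TOOLS,
) -> List[VariantRecord]:
    """Draw per-tool raw scores for every record per the accuracy spec.

    Each tool independently: withholds its score at ``missing_rate``; else
    calls the correct side with the regional sensitivity/specificity, softens
    to a "possibly" category at ``possibly_rate``, and emits the raw score at
    the midpoint of the chosen category's threshold band — so mapping the raw
    score back to a category inverts the simulation exactly.  Returns new
    records with ``tool_scores`` filled; inputs untouched.
    """
    missing_spec_tools = [t for t in tools if t not in spec.sensitivity]
    if missing_spec_tools:
        raise ValueError(f"spec does not cover tools: {missing_spec_tools}")
    rng = np.random.default_rng(seed)
    out: List[VariantRecord] = []
    from dataclasses import replace

    for rec in records:
        label = truth[rec.key]
        region = f"{rec.key[0]}:{rec.pos // bin_size}"
        scores: Dict[str, float] = {}
        for tool in tools:
            sens, spc, miss, poss = spec.rates(tool, region)
            if rng.random() < miss:
                continue
            p_correct = sens if label == "pathogenic" else spc
            correct = rng.random() < p_correct
            damaging_side = correct if label == "pathogenic" else not correct
            soften = rng.random() < poss
            if damaging_side:
                cat = POSSIBLY_DAMAGING if soften else DAMAGING
            else:
                cat = POSSIBLY_BENIGN if soften else BENIGN
            scores[tool] = category_band_midpoint(tool, cat, thresholds)
        out.append(replace(rec, tool_scores=scores))
    return out


# ---------------------------------------------------------------------------
# Gene-phenotype database


def build_gene_phenotype_db(
    n_genes: int,
    n_diseases: int,
    category_table: Optional[pd.DataFrame] = None,
    terms_per_disease: Tuple[int, int] = (3, 6),
    seed: int = 0,
) -> GenePhenotypeDB:
    """A synthetic gene-phenotype-disease database.

    Diseases are assigned to the panel's 19 clinical categories with
    probability proportional to the published per-category disease counts;
    each disease gets 1-2 genes, an inheritance mode (AD/AR, XL for X-linked
    flavor) and a mostly-unique phenotype term set drawn from a universe of
    ``5 * n_diseases`` terms.  Deterministic per seed.
    """
    if n_diseases < 1:
        raise ValueError("n_diseases must be >= 1")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if category_table is None:
        from .variants import load_disease_category_table

        category_table = load_disease_category_table()
    rng = np.random.default_rng(seed)
    cats = list(category_table["category"])
    counts = np.asarray(category_table["n_diseases"], dtype=float)
    probs = counts / counts.sum()

    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    n_terms = 5 * n_diseases
    term_universe = [f"HP:{i:07d}" for i in range(n_terms)]

    db = GenePhenotypeDB()
    lo, hi = terms_per_disease
    for i in range(n_diseases):
        did = f"D{i:05d}"
        category = cats[int(rng.choice(len(cats), p=probs))]
        inheritance = str(rng.choice(["AD", "AR", "XL"], p=[0.45, 0.45, 0.10]))
        n_g = int(rng.integers(1, 3))
        d_genes = tuple(sorted(str(g) for g in rng.choice(genes, size=n_g, replace=False)))
        k = int(rng.integers(lo, hi + 1))
        d_terms = {str(t) for t in rng.choice(term_universe, size=k, replace=False)}
        db.diseases[did] = DiseaseRecord(did, f"Disease {i}", category, inheritance, d_genes, d_terms)
        for g in d_genes:
            db.gene_to_diseases.setdefault(g, set()).add(did)
            for t in d_terms:
                db.phenotype_to_genes.setdefault(t, set()).add(g)
    # genes not linked to any disease still exist in the gene universe but are
    # omitted from the maps; db.genes is the diseasome's gene set
    db.validate()
    return db


# ---------------------------------------------------------------------------
# Simulated patients


@dataclass
class PatientSpec:
    """Recipe for one simulated patient."""

    disease_id: str
    n_background_variants: int = 50
    phenotype_noise_drop: int = 0   # disease terms withheld from the patient
    phenotype_noise_add: int = 0    # unrelated terms added
    seed: int = 0


@dataclass
class SimulatedPatient:
    patient_id: str
    records: List[VariantRecord]
    terms: List[str]
    disease_id: str
    causal_gene: str
    causal_keys: List[Tuple[str, int, str, str]]


_CAUSAL_CONSEQUENCES = ("nonsense", "frameshift", "missense")


def simulate_patient(
    db: GenePhenotypeDB,
    spec: PatientSpec,
    genome: Optional[Mapping[str, int]] = None,
    patient_id: Optional[str] = None,
) -> SimulatedPatient:
    """One patient: implanted causal variant(s), filterable background, noisy
    phenotype terms.

    The causal variant honors the disease's inheritance mode (AR: two
    compound-het records or one hom; XL: one hemizygous record on X; AD: one
    het), is absent from population databases (no allele frequency) and
    carries a curated DM class.  Background variants are common
    (AF drawn from [0.01, 0.5]) and curated-absent, so the default step-1
    filter removes all of them by construction.
    """
    if spec.disease_id not in db.diseases:
        raise ValueError(f"disease not in database: {spec.disease_id}")
    genome = genome or DEFAULT_GENOME
    rng = np.random.default_rng(spec.seed)
    disease = db.diseases[spec.disease_id]
    gene = str(rng.choice(sorted(disease.genes)))

    def _snv(chrom, pos, zyg, conseq, gene_name, af=None, hgmd="absent"):
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[int(rng.integers(4))]
        while alt == ref:
            alt = _BASES[int(rng.integers(4))]
        return VariantRecord(
            chrom, pos, ref, alt, "SNV",
            gene=gene_name, consequence=conseq, zygosity=zyg,
            allele_freq=af, hgmd=hgmd,
        )

    records: List[VariantRecord] = []
    mode = disease.inheritance
    causal_chrom = "X" if mode == "XL" else str(rng.choice([c for c in genome if c != "X"]))
    base_pos = int(rng.integers(1, genome[causal_chrom] - 10_000))
    conseq = str(rng.choice(_CAUSAL_CONSEQUENCES))
    if mode == "AR":
        if rng.random() < 0.5:
            records.append(_snv(causal_chrom, base_pos, "hom", conseq, gene, hgmd="DM"))
        else:
            records.append(_snv(causal_chrom, base_pos, "het", conseq, gene, hgmd="DM"))
            records.append(
                _snv(causal_chrom, base_pos + 500, "het",
                     str(rng.choice(_CAUSAL_CONSEQUENCES)), gene, hgmd="DM")
            )
    elif mode == "XL":
        records.append(_snv(causal_chrom, base_pos, "hemi", conseq, gene, hgmd="DM"))
    else:  # AD or unknown
        records.append(_snv(causal_chrom, base_pos, "het", conseq, gene, hgmd="DM"))
    causal_keys = [r.key for r in records]

    background_genes = sorted(db.genes - set(disease.genes)) or [None]
    for _ in range(spec.n_background_variants):
        chrom, pos = _random_position(rng, genome)
        g = background_genes[int(rng.integers(len(background_genes)))] if background_genes[0] else None
        af = float(rng.uniform(0.01, 0.5))
        conseq_bg = str(rng.choice(["missense", "synonymous"], p=[0.6, 0.4]))
        zyg = str(rng.choice(["het", "hom"], p=[0.8, 0.2]))
        records.append(_snv(chrom, pos, zyg, conseq_bg, g, af=af))

    terms = sorted(disease.terms)
    if spec.phenotype_noise_drop:
        n_drop = min(spec.phenotype_noise_drop, max(len(terms) - 1, 0))
        drop = set(rng.choice(terms, size=n_drop, replace=False)) if n_drop else set()
        terms = [t for t in terms if t not in drop]
    if spec.phenotype_noise_add:
        pool = sorted(set(db.phenotype_to_genes) - set(terms))
        if pool:
            add = rng.choice(pool, size=min(spec.phenotype_noise_add, len(pool)), replace=False)
            terms = terms + [str(t) for t in add]

    return SimulatedPatient(
        patient_id or f"patient_{spec.disease_id}_{spec.seed}",
        records,
        terms,
        spec.disease_id,
        gene,
        causal_keys,
    )


def write_patient_files(patient: SimulatedPatient, out_dir: str) -> Tuple[str, str]:
    """Emit the patient's VCF (annotations carried in INFO) and one-term-per-
    line phenotype file; returns (vcf_path, phenotype_path)."""
    import os

    from ._util import atomic_write_text
    from .variants import write_vcf

    os.makedirs(out_dir, exist_ok=True)
    vcf_path = os.path.join(out_dir, f"{patient.patient_id}.vcf")
    txt_path = os.path.join(out_dir, f"{patient.patient_id}.phenotypes.txt")
    write_vcf(patient.records, vcf_path)
    atomic_write_text(txt_path, "\n".join(patient.terms) + "\n")
    return vcf_path, txt_path


def simulate_cohort(
    db: GenePhenotypeDB,
    n_patients: int,
    seed: int = 0,
    n_background_variants: int = 50,
    phenotype_noise_drop: int = 0,
    phenotype_noise_add: int = 0,
) -> List[SimulatedPatient]:
    """A cohort of patients with independently drawn implanted diseases."""
    rng = np.random.default_rng(seed)
    ids = sorted(db.diseases)
    out = []
    for i in range(n_patients):
        did = str(ids[int(rng.integers(len(ids)))])
        spec = PatientSpec(
            did,
            n_background_variants=n_background_variants,
            phenotype_noise_drop=phenotype_noise_drop,
            phenotype_noise_add=phenotype_noise_add,
            seed=int(rng.integers(2**31 - 1)),
        )
        out.append(simulate_patient(db, spec, patient_id=f"P{i:04d}"))
    return out
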