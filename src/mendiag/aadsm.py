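"""Automated variant filtering, scoring and phenotype-driven disease ranking.

The diagnosis pipeline runs three steps on one patient:

1. **Filter & phenotype analysis.**  Annotated variants are filtered on
   population frequency (common variants are dropped unless a curated
   pathogenicity class rescues them), consequence (synonymous changes away
   from splice sites are dropped) and, when a panel manifest is supplied, on
   membership in the captured intervals (exons plus 10 bp of flanking
   intron).  In parallel the patient's phenotype terms are mapped to a scored
   gene list.
2. **Scoring.**  Every surviving variant receives an integer score summing
   points for rarity, variant type, coding consequence, curated
   pathogenicity class and the ensemble classification.
3. **Ranking & reporting.**  Candidate diseases (those with at least one
   scored variant in one of their genes) are ranked by a score combining the
   best variant support in the disease's genes, the phenotype-term overlap
   with the disease, and inheritance-mode consistency; a machine-readable
   JSON report and an HTML page are written.

All point tables and cut-offs are configuration, not constants.
"""

from __future__ import annotations

import hashlib
import html
import json
import os
import warnings
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from ._util import MendiagError, atomic_write_text, norm_chrom
from .mpps import MppsResult
from .variants import VariantRecord

INHERITANCE_MODES = ("AD", "AR", "XL", "unknown")


# ---------------------------------------------------------------------------
# Gene-phenotype database


@dataclass
class DiseaseRecord:
    disease_id: str
    name: str
    category: str
    inheritance: str
    genes: Tuple[str, ...]
    terms: Set[str]


@dataclass
class GenePhenotypeDB:
    """Phenotype→genes, gene→diseases and per-disease metadata.

    The phenotype vocabulary is any controlled set of term strings (HPO ids
    work fine); matching is by exact term, no ontology expansion.
    """

    phenotype_to_genes: Dict[str, Set[str]] = field(default_factory=dict)
    gene_to_diseases: Dict[str, Set[str]] = field(default_factory=dict)
    diseases: Dict[str, DiseaseRecord] = field(default_factory=dict)

    def validate(self) -> None:
        for d in self.diseases.values():
            if d.inheritance not in INHERITANCE_MODES:
                raise MendiagError(f"{d.disease_id}: unknown inheritance {d.inheritance!r}")
            for g in d.genes:
                if d.disease_id not in self.gene_to_diseases.get(g, set()):
                    raise MendiagError(f"{d.disease_id}: gene {g} not in gene->diseases map")

    @property
    def genes(self) -> Set[str]:
        return set(self.gene_to_diseases)

    # -- TSV round-trip (phenotype_gene.tsv, gene_disease.tsv, disease_meta.tsv)

    @classmethod
    def from_dir(cls, path: str) -> "GenePhenotypeDB":
        db = cls()
        pg = pd.read_csv(os.path.join(path, "phenotype_gene.tsv"), sep="\t")
        for _, row in pg.iterrows():
            db.phenotype_to_genes.setdefault(str(row["term"]), set()).add(str(row["gene"]))
        gd = pd.read_csv(os.path.join(path, "gene_disease.tsv"), sep="\t")
        for _, row in gd.iterrows():
            db.gene_to_diseases.setdefault(str(row["gene"]), set()).add(str(row["disease_id"]))
        meta = pd.read_csv(os.path.join(path, "disease_meta.tsv"), sep="\t")
        for _, row in meta.iterrows():
            did = str(row["disease_id"])
            genes = tuple(sorted(g for g, ds in db.gene_to_diseases.items() if did in ds))
            terms = set(str(row["terms"]).split(";")) if str(row["terms"]) else set()
            db.diseases[did] = DiseaseRecord(
                did, str(row["name"]), str(row["category"]), str(row["inheritance"]),
                genes, terms,
            )
        db.validate()
        return db

    def to_dir(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        rows = [
            {"term": t, "gene": g}
            for t in sorted(self.phenotype_to_genes)
            for g in sorted(self.phenotype_to_genes[t])
        ]
        pd.DataFrame(rows, columns=["term", "gene"]).to_csv(
            os.path.join(path, "phenotype_gene.tsv"), sep="\t", index=False
        )
        rows = [
            {"gene": g, "disease_id": d}
            for g in sorted(self.gene_to_diseases)
            for d in sorted(self.gene_to_diseases[g])
        ]
        pd.DataFrame(rows, columns=["gene", "disease_id"]).to_csv(
            os.path.join(path, "gene_disease.tsv"), sep="\t", index=False
        )
        rows = [
            {
                "disease_id": d.disease_id,
                "name": d.name,
                "category": d.category,
                "inheritance": d.inheritance,
                "terms": ";".join(sorted(d.terms)),
            }
            for d in sorted(self.diseases.values(), key=lambda d: d.disease_id)
        ]
        pd.DataFrame(
            rows, columns=["disease_id", "name", "category", "inheritance", "terms"]
        ).to_csv(os.path.join(path, "disease_meta.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Step 1: filtering and the phenotype gene list


@dataclass
class FilterConfig:
    """Step-1 filter thresholds."""

    freq_cutoff: float = 0.01          # drop at or above, unless curated DM/DM?
    rescue_classes: Tuple[str, ...] = ("DM", "DM?")
    drop_synonymous: bool = True       # unless flagged within 2 bp of a splice site


PanelManifest = Mapping[str, Sequence[Tuple[int, int]]]  # chrom -> [(start, end)] 1-based closed


def _in_panel(record: VariantRecord, panel: PanelManifest) -> bool:
    intervals = panel.get(norm_chrom(record.chrom), ())
    end = record.end if record.end is not None else record.pos
    return any(record.pos <= b and end >= a for a, b in intervals)


def filter_variants(
    records: Sequence[VariantRecord],
    config: Optional[FilterConfig] = None,
    panel: Optional[PanelManifest] = None,
) -> List[VariantRecord]:
    """Step-1 variant filter; order preserved, idempotent.

    Drops common variants (allele frequency at or above the cutoff) unless a
    curated DM/DM? class rescues them; drops synonymous changes not flagged
    near a splice site; drops variants outside the captured intervals when a
    panel manifest is given.
    """
    cfg = config or FilterConfig()
    kept = []
    for r in records:
        if (
            r.allele_freq is not None
            and r.allele_freq >= cfg.freq_cutoff
            and r.hgmd not in cfg.rescue_classes
        ):
            continue
        if cfg.drop_synonymous and r.consequence == "synonymous" and not r.near_splice:
            continue
        if panel is not None and not _in_panel(r, panel):
            continue
        kept.append(r)
    return kept


def phenotype_gene_list(
    terms: Sequence[str], db: GenePhenotypeDB
) -> List[Tuple[str, int]]:
    """Score every gene in the database by how many input phenotype terms
    link to it.  Genes hit by no term stay in the list with score 0 (this is
    a ranking, not an exclusion).  Unknown terms warn and are skipped."""
    if not db.genes:
        raise MendiagError("gene-phenotype database is empty")
    scores: Dict[str, int] = {g: 0 for g in db.genes}
    for term in terms:
        genes = db.phenotype_to_genes.get(term)
        if genes is None:
            warnings.warn(f"phenotype term not in database: {term!r}", stacklevel=2)
            continue
        for g in genes:
            scores[g] = scores.get(g, 0) + 1
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# Step 2: variant scoring


@dataclass
class ScoringRules:
    """Default point table for the four scoring inputs plus the ensemble
    call.  Magnitudes are package defaults, fully overridable."""

    freq_bands: Tuple[Tuple[float, int], ...] = (
        (1e-4, 4),   # AF < 1e-4 (or absent from population databases)
        (0.005, 2),
        (0.01, 1),
    )
    freq_common: int = -6  # AF >= 0.01
    cnv_type_pts: int = 4  # whole-gene / multi-exon copy-number events
    consequence_pts: Mapping[str, int] = field(
        default_factory=lambda: {
            "nonsense": 4,
            "frameshift": 4,
            "splicing": 4,
            "inframe_indel": 3,
            "missense": 2,
            "synonymous": -4,
            "other": 0,
        }
    )
    hgmd_pts: Mapping[str, int] = field(
        default_factory=lambda: {"DM": 4, "DM?": 2, "DP": 1, "DFP": 1, "absent": 0}
    )
    mpps_damaging: int = 2
    mpps_benign: int = -2


@dataclass
class VariantScore:
    """Integer score components for one variant; total is their sum."""

    freq_pts: int
    type_pts: int
    consequence_pts: int
    hgmd_pts: int
    mpps_pts: int

    @property
    def total(self) -> int:
        return self.freq_pts + self.type_pts + self.consequence_pts + self.hgmd_pts + self.mpps_pts


def score_variant(
    record: VariantRecord,
    mpps_result: Optional[MppsResult] = None,
    rules: Optional[ScoringRules] = None,
) -> VariantScore:
    """Score one annotated variant on rarity, type, consequence, curated
    class and ensemble call."""
    r = rules or ScoringRules()
    af = record.allele_freq
    if af is None:
        freq_pts = r.freq_bands[0][1]
    else:
        for cut, pts in r.freq_bands:
            if af < cut:
                freq_pts = pts
                break
        else:
            freq_pts = r.freq_common
    type_pts = r.cnv_type_pts if record.is_cnv else 0
    conseq_pts = r.consequence_pts.get(record.consequence, 0)
    hgmd_pts = r.hgmd_pts.get(record.hgmd, 0)
    mpps_pts = 0
    if mpps_result is not None:
        if mpps_result.classification == "damaging":
            mpps_pts = r.mpps_damaging
        elif mpps_result.classification == "benign":
            mpps_pts = r.mpps_benign
    return VariantScore(freq_pts, type_pts, conseq_pts, hgmd_pts, mpps_pts)


# ---------------------------------------------------------------------------
# Step 3: disease ranking


@dataclass
class DiseaseScore:
    """One candidate disease with the evidence behind its rank."""

    disease_id: str
    name: str
    gene: str
    phenotype_match: float       # fraction of the disease's terms the patient shows
    variant_support: int         # best variant total among the disease's genes
    inheritance_consistent: bool
    total: float


def _inheritance_consistent(
    mode: str, gene_variants: Sequence[Tuple[VariantRecord, VariantScore]]
) -> bool:
    zygs = [rec.zygosity for rec, _ in gene_variants]
    if mode == "AD":
        return len(zygs) >= 1
    if mode == "AR":
        return zygs.count("het") >= 2 or any(z in ("hom", "hemi") for z in zygs)
    if mode == "XL":
        return any(z in ("hemi", "hom") for z in zygs)
    return False


def rank_diseases(
    scored_variants: Sequence[Tuple[VariantRecord, VariantScore]],
    gene_list: Sequence[Tuple[str, int]],
    db: GenePhenotypeDB,
    patient_terms: Sequence[str],
    max_rank: int = 100,
) -> List[DiseaseScore]:
    """Rank every disease with at least one scored variant in its genes.

    ``total = variant_support * (1 + phenotype_match) + 2 * inheritance_consistent``
    where ``phenotype_match`` is the fraction of the disease's phenotype terms
    present in the patient's terms (0 for diseases without terms).  Sorted by
    total descending, ties broken by disease id ascending; capped at
    ``max_rank`` entries.
    """
    by_gene: Dict[str, List[Tuple[VariantRecord, VariantScore]]] = {}
    for rec, sc in scored_variants:
        if rec.gene:
            by_gene.setdefault(rec.gene, []).append((rec, sc))
    terms = set(patient_terms)
    out: List[DiseaseScore] = []
    for did in sorted(db.diseases):
        d = db.diseases[did]
        hit_genes = [g for g in d.genes if g in by_gene]
        if not hit_genes:
            continue
        match = (len(terms & d.terms) / len(d.terms)) if d.terms else 0.0
        best_gene = ""
        support = None
        consistent = False
        for g in hit_genes:
            g_support = max(sc.total for _, sc in by_gene[g])
            if support is None or g_support > support:
                support, best_gene = g_support, g
                consistent = _inheritance_consistent(d.inheritance, by_gene[g])
        total = support * (1.0 + match) + 2.0 * consistent
        out.append(DiseaseScore(did, d.name, best_gene, match, support, consistent, total))
    out.sort(key=lambda s: (-s.total, s.disease_id))
    return out[:max_rank]


# ---------------------------------------------------------------------------
# Reporting


def _config_hash(config: Optional[Mapping]) -> str:
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def report_dict(
    patient_id: str,
    terms: Sequence[str],
    ranked_diseases: Sequence[DiseaseScore],
    ranked_variants: Sequence[Tuple[VariantRecord, VariantScore]],
    config: Optional[Mapping] = None,
    timestamp: Optional[str] = None,
) -> Dict:
    from . import __version__

    return {
        "patient_id": patient_id,
        "phenotype_terms": list(terms),
        "diseases": [
            {
                "rank": i + 1,
                "disease_id": s.disease_id,
                "name": s.name,
                "gene": s.gene,
                "phenotype_match": round(s.phenotype_match, 6),
                "variant_support": s.variant_support,
                "inheritance_consistent": s.inheritance_consistent,
                "total": round(s.total, 6),
            }
            for i, s in enumerate(ranked_diseases)
        ],
        "variants": [
            {
                "rank": i + 1,
                "chrom": norm_chrom(rec.chrom),
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "var_type": rec.var_type,
                "gene": rec.gene,
                "consequence": rec.consequence,
                "zygosity": rec.zygosity,
                "allele_freq": rec.allele_freq,
                "hgmd": rec.hgmd,
                "freq_pts": sc.freq_pts,
                "type_pts": sc.type_pts,
                "consequence_pts": sc.consequence_pts,
                "hgmd_pts": sc.hgmd_pts,
                "mpps_pts": sc.mpps_pts,
                "total": sc.total,
            }
            for i, (rec, sc) in enumerate(ranked_variants)
        ],
        "provenance": {
            "package": "mendiag",
            "version": __version__,
            "config_hash": _config_hash(config),
            "timestamp": timestamp
            or datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ"),
        },
    }


def _html_table(rows: Sequence[Mapping], columns: Sequence[str]) -> str:
    head = "".join(f"<th>{html.escape(c)}</th>" for c in columns)
    body = []
    for row in rows:
        cells = "".join(
            f"<td>{html.escape('' if row.get(c) is None else str(row.get(c)))}</td>"
            for c in columns
        )
        body.append(f"<tr>{cells}</tr>")
    return f"<table><thead><tr>{head}</tr></thead><tbody>{''.join(body)}</tbody></table>"


def render_html(report: Mapping) -> str:
    disease_cols = (
        "rank", "disease_id", "name", "gene", "phenotype_match",
        "variant_support", "inheritance_consistent", "total",
    )
    variant_cols = (
        "rank", "chrom", "pos", "ref", "alt", "var_type", "gene", "consequence",
        "zygosity", "allele_freq", "hgmd", "freq_pts", "type_pts",
        "consequence_pts", "hgmd_pts", "mpps_pts", "total",
    )
    prov = report["provenance"]
    terms = ", ".join(html.escape(t) for t in report["phenotype_terms"])
    return f"""<!DOCTYPE html>
<html><head><meta charset="utf-8">
<title>Diagnosis report {html.escape(report['patient_id'])}</title>
<style>body{{font-family:sans-serif;margin:2em}}table{{border-collapse:collapse;margin:1em 0}}
td,th{{border:1px solid #999;padding:0.25em 0.6em;text-align:left}}</style>
</head><body>
<h1>Diagnosis report: {html.escape(report['patient_id'])}</h1>
<p><b>Phenotype terms:</b> {terms or '(none)'}</p>
<h2>Ranked candidate diseases</h2>
{_html_table(report['diseases'], disease_cols) if report['diseases'] else '<p>No candidate diseases.</p>'}
<h2>Ranked variants</h2>
{_html_table(report['variants'], variant_cols) if report['variants'] else '<p>No variants survived filtering.</p>'}
<p><small>mendiag {html.escape(prov['version'])} · config {html.escape(prov['config_hash'])} · {html.escape(prov['timestamp'])}</small></p>
</body></html>
"""


def generate_report(
    patient_id: str,
    terms: Sequence[str],
    ranked_diseases: Sequence[DiseaseScore],
    ranked_variants: Sequence[Tuple[VariantRecord, VariantScore]],
    out_dir: str,
    config: Optional[Mapping] = None,
    timestamp: Optional[str] = None,
) -> Tuple[str, str]:
    """Write the JSON report and its HTML rendering; returns both paths.

    Deterministic given fixed inputs and a ``timestamp`` override.
    """
    os.makedirs(out_dir, exist_ok=True)
    rep = report_dict(patient_id, terms, ranked_diseases, ranked_variants, config, timestamp)
    json_path = os.path.join(out_dir, f"{patient_id}.json")
    html_path = os.path.join(out_dir, f"{patient_id}.html")
    atomic_write_text(json_path, json.dumps(rep, indent=2, sort_keys=True) + "\n")
    atomic_write_text(html_path, render_html(rep))
    return json_path, html_path


def load_report(path: str) -> Dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# End-to-end convenience


def diagnose_patient(
    patient_id: str,
    records: Sequence[VariantRecord],
    terms: Sequence[str],
    db: GenePhenotypeDB,
    mpps_results: Optional[Mapping[Tuple, MppsResult]] = None,
    filter_config: Optional[FilterConfig] = None,
    rules: Optional[ScoringRules] = None,
    panel: Optional[PanelManifest] = None,
    max_rank: int = 100,
    out_dir: Optional[str] = None,
    timestamp: Optional[str] = None,
    config: Optional[Mapping] = None,
) -> Dict:
    """Filter, score, rank and (optionally) report for one patient.

    ``mpps_results`` maps variant keys to ensemble results for the optional
    ensemble component of the variant score.  Returns the report dict; writes
    files when ``out_dir`` is given.
    """
    kept = filter_variants(records, filter_config, panel)
    genes = phenotype_gene_list(terms, db)
    scored = [
        (r, score_variant(r, (mpps_results or {}).get(r.key), rules)) for r in kept
    ]
    scored.sort(key=lambda rs: (-rs[1].total, rs[0].key))
    diseases = rank_diseases(scored, genes, db, terms, max_rank=max_rank)
    rep = report_dict(patient_id, terms, diseases, scored, config, timestamp)
    if out_dir is not None:
        generate_report(
            patient_id, terms, diseases, scored, out_dir, config, timestamp
        )
    return rep
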