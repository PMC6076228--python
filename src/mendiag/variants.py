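"""Variant records, VCF I/O, annotation joins and bundled reference tables.

Coordinates are 1-based fully closed, exactly as printed in VCF.  Copy-number
events arrive as symbolic ALT alleles (``<DEL>``, ``<DUP>``) with an ``END``
INFO key and are treated as whole-gene events when they span at least one
full gene interval.  Multi-allelic lines are split into one record per ALT.

Annotation databases (population frequency, curated pathogenicity classes,
per-tool deleteriousness scores) are headered TSVs keyed on
``(chrom, pos, ref, alt)`` with chromosome labels normalized by stripping a
leading ``chr``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import pysam

from ._util import MendiagError, atomic_write_text, norm_chrom
from .predictors import TOOLS

VAR_TYPES = ("SNV", "INDEL", "CNV_DEL", "CNV_DUP")
CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "splicing",
    "synonymous",
    "other",
)
ZYGOSITIES = ("het", "hom", "hemi", "unknown")
HGMD_CLASSES = ("DM", "DM?", "DP", "DFP", "absent")

VariantKey = Tuple[str, int, str, str]


class VcfFormatError(MendiagError):
    """Malformed or header-less VCF input."""


class AnnotationError(MendiagError):
    """Malformed annotation database."""


@dataclass
class VariantRecord:
    """One called variant (SNV, small indel, or CNV as a symbolic allele).

    Annotation fields (``allele_freq``, ``hgmd``, ``tool_scores``,
    ``near_splice``) start empty and are filled by :func:`annotate`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    var_type: str
    gene: Optional[str] = None
    consequence: str = "other"
    zygosity: str = "unknown"
    allele_freq: Optional[float] = None
    end: Optional[int] = None
    near_splice: bool = False
    hgmd: str = "absent"
    tool_scores: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.var_type not in VAR_TYPES:
            raise ValueError(f"unknown var_type: {self.var_type!r}")
        if self.var_type in ("SNV", "INDEL") and (not self.ref or not self.alt):
            raise ValueError("ref/alt must be non-empty for SNV/INDEL")
        if self.var_type == "SNV" and not (len(self.ref) == 1 and len(self.alt) == 1):
            raise ValueError("SNV requires single-base ref and alt")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence: {self.consequence!r}")
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity: {self.zygosity!r}")
        if self.allele_freq is not None and not (0.0 <= self.allele_freq <= 1.0):
            raise ValueError(f"allele_freq outside [0,1]: {self.allele_freq}")

    @property
    def key(self) -> VariantKey:
        return (norm_chrom(self.chrom), self.pos, self.ref, self.alt)

    @property
    def is_cnv(self) -> bool:
        return self.var_type in ("CNV_DEL", "CNV_DUP")


def infer_var_type(ref: str, alt: str) -> str:
    """SNV iff both alleles are single bases; symbolic ALT -> CNV type."""
    if alt == "<DEL>":
        return "CNV_DEL"
    if alt == "<DUP>":
        return "CNV_DUP"
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    return "INDEL"


def _zygosity_from_gt(gt: Optional[Sequence[Optional[int]]], alt_index: int) -> str:
    if not gt or all(a is None for a in gt):
        return "unknown"
    hits = sum(1 for a in gt if a == alt_index)
    if len(gt) == 1:
        return "hemi" if hits == 1 else "unknown"
    if hits >= 2:
        return "hom"
    if hits == 1:
        return "het"
    return "unknown"


def _info_get(info, key, default=None):
    # pysam raises for INFO keys absent from the header; treat as missing
    try:
        if key in info:
            return info[key]
    except (KeyError, ValueError):
        pass
    return default


def _record_from_pysam(rec, alt: str, alt_index: int) -> VariantRecord:
    info = rec.info
    vt = infer_var_type(rec.ref, alt)
    af = None
    if _info_get(info, "AF") is not None:
        raw_af = info["AF"]
        if isinstance(raw_af, tuple):
            raw_af = raw_af[alt_index - 1] if alt_index - 1 < len(raw_af) else raw_af[0]
        if raw_af is not None:
            af = float(raw_af)
    zyg = "unknown"
    if rec.samples:
        sample = rec.samples[0]
        zyg = _zygosity_from_gt(sample.get("GT"), alt_index)
    else:
        z = _info_get(info, "ZYG")
        if z in ZYGOSITIES:
            zyg = z
    end = rec.stop if vt in ("CNV_DEL", "CNV_DUP") else None
    return VariantRecord(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref,
        alt=alt,
        var_type=vt,
        gene=_info_get(info, "GENE"),
        consequence=_info_get(info, "CONSEQ", "other"),
        zygosity=zyg,
        allele_freq=af,
        end=end,
        near_splice=bool(_info_get(info, "NEAR_SPLICE", False)),
        hgmd=_info_get(info, "HGMD", "absent"),
    )


def read_vcf(path: str) -> List[VariantRecord]:
    """Read a VCF into VariantRecords, one per ALT allele, in file order.

    Symbolic ALTs ``<DEL>``/``<DUP>`` become CNV records.  A file without a
    VCF header raises :class:`VcfFormatError`; an unparseable data line
    raises :class:`VcfFormatError` naming the (approximate) line number.
    """
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise VcfFormatError(f"{path}: not a valid VCF (missing or bad header): {exc}") from exc
    n_header = len(str(vf.header).rstrip("\n").split("\n"))
    out: List[VariantRecord] = []
    n_lines = 0
    try:
        for rec in vf:
            n_lines += 1
            for i, alt in enumerate(rec.alts or (), start=1):
                out.append(_record_from_pysam(rec, alt, i))
    except (ValueError, OSError) as exc:
        raise VcfFormatError(
            f"{path}: unparseable data line {n_header + n_lines + 1}: {exc}"
        ) from exc
    finally:
        vf.close()
    return out


_INFO_LINES = (
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=CONSEQ,Number=1,Type=String,Description="Coding consequence">',
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">',
    '##INFO=<ID=HGMD,Number=1,Type=String,Description="Curated pathogenicity class">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of CNV">',
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
    '##INFO=<ID=NEAR_SPLICE,Number=0,Type=Flag,Description="Within 2 bp of a splice site">',
    '##INFO=<ID=PROBAND,Number=1,Type=String,Description="Proband identifier">',
)

_MPPS_INFO_LINES = (
    '##INFO=<ID=MPPS_SCORE_DMG,Number=1,Type=Float,Description="Ensemble damaging-side score">',
    '##INFO=<ID=MPPS_SCORE_BEN,Number=1,Type=Float,Description="Ensemble benign-side score">',
    '##INFO=<ID=MPPS_CLASS,Number=1,Type=String,Description="Ensemble classification">',
    '##INFO=<ID=MPPS_MISCLASS,Number=0,Type=Flag,Description="No trio round reached agreement">',
    '##INFO=<ID=MPPS_ROUND,Number=1,Type=Integer,Description="Trio round at termination">',
)

_GT_BY_ZYG = {"het": (0, 1), "hom": (1, 1), "hemi": (1,), "unknown": (None, None)}


def write_vcf(
    records: Sequence[VariantRecord],
    path: str,
    mpps_results: Optional[Sequence] = None,
    extra_info: Optional[Sequence[Mapping[str, object]]] = None,
) -> None:
    """Write records as VCF v4.2, with a single-sample GT carrying zygosity.

    ``mpps_results`` (parallel to ``records``) adds MPPS_* INFO keys;
    ``extra_info`` (parallel mappings) adds arbitrary pre-declared keys such
    as PROBAND.
    """
    if mpps_results is not None and len(mpps_results) != len(records):
        raise ValueError("mpps_results must parallel records")
    header = pysam.VariantHeader()
    seen = []
    for r in records:
        if r.chrom not in seen:
            seen.append(r.chrom)
    for c in seen:
        header.contigs.add(c)
    for line in _INFO_LINES:
        header.add_line(line)
    if mpps_results is not None:
        for line in _MPPS_INFO_LINES:
            header.add_line(line)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample("SAMPLE")
    vf = pysam.VariantFile(path, "w", header=header)
    try:
        for i, r in enumerate(records):
            rec = vf.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt)
            )
            if r.is_cnv:
                rec.info["SVTYPE"] = "DEL" if r.var_type == "CNV_DEL" else "DUP"
                if r.end is not None:
                    rec.stop = r.end
            if r.gene:
                rec.info["GENE"] = r.gene
            rec.info["CONSEQ"] = r.consequence
            if r.allele_freq is not None:
                rec.info["AF"] = (r.allele_freq,)
            if r.hgmd != "absent":
                rec.info["HGMD"] = r.hgmd
            if r.near_splice:
                rec.info["NEAR_SPLICE"] = True
            if extra_info is not None:
                for k, v in extra_info[i].items():
                    rec.info[k] = v
            if mpps_results is not None:
                m = mpps_results[i]
                rec.info["MPPS_SCORE_DMG"] = round(m.score_dmg, 4)
                rec.info["MPPS_SCORE_BEN"] = round(m.score_ben, 4)
                rec.info["MPPS_CLASS"] = m.classification
                if m.mis_classified:
                    rec.info["MPPS_MISCLASS"] = True
                rec.info["MPPS_ROUND"] = m.round_used
            rec.samples["SAMPLE"]["GT"] = _GT_BY_ZYG[r.zygosity]
            vf.write(rec)
    finally:
        vf.close()


# ---------------------------------------------------------------------------
# Annotation databases


@dataclass
class AnnotationDB:
    """Local annotation tables keyed on (chrom, pos, ref, alt).

    ``freq_table`` maps to a population allele frequency, ``hgmd_table`` to a
    curated class (DM, DM?, DP, DFP), ``tool_table`` to raw scores for any
    subset of the 17 canonical deleteriousness tools.
    """

    freq_table: Dict[VariantKey, float] = field(default_factory=dict)
    hgmd_table: Dict[VariantKey, str] = field(default_factory=dict)
    tool_table: Dict[VariantKey, Dict[str, float]] = field(default_factory=dict)

    @staticmethod
    def _key_from_row(row) -> VariantKey:
        return (norm_chrom(str(row.chrom)), int(row.pos), str(row.ref), str(row.alt))

    @classmethod
    def from_tsvs(
        cls,
        freq_path: Optional[str] = None,
        hgmd_path: Optional[str] = None,
        tool_path: Optional[str] = None,
    ) -> "AnnotationDB":
        db = cls()
        if freq_path:
            df = pd.read_csv(freq_path, sep="\t", dtype={"chrom": str})
            for row in df.itertuples():
                db.freq_table[cls._key_from_row(row)] = float(row.allele_freq)
        if hgmd_path:
            df = pd.read_csv(hgmd_path, sep="\t", dtype={"chrom": str})
            for row in df.itertuples():
                if row.hgmd_class not in HGMD_CLASSES:
                    raise AnnotationError(f"unknown pathogenicity class {row.hgmd_class!r}")
                db.hgmd_table[cls._key_from_row(row)] = str(row.hgmd_class)
        if tool_path:
            df = pd.read_csv(tool_path, sep="\t", dtype={"chrom": str})
            tool_cols = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
            bad = [c for c in tool_cols if c not in TOOLS]
            if bad:
                raise AnnotationError(f"unknown tool column(s): {bad}")
            # iterrows, not itertuples: tool names like M-CAP are not identifiers
            for _, row in df.iterrows():
                key = (norm_chrom(str(row["chrom"])), int(row["pos"]), str(row["ref"]), str(row["alt"]))
                scores = {}
                for tool in tool_cols:
                    val = row[tool]
                    if pd.isna(val) or val == "":
                        continue
                    try:
                        scores[tool] = float(val)
                    except (TypeError, ValueError):
                        raise AnnotationError(
                            f"non-numeric raw score for tool {tool!r} at {key}: {val!r}"
                        ) from None
                db.tool_table[key] = scores
        return db

    def to_tsvs(self, freq_path: str, hgmd_path: str, tool_path: str) -> None:
        rows = [
            {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "allele_freq": v}
            for k, v in self.freq_table.items()
        ]
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "allele_freq"]).to_csv(
            freq_path, sep="\t", index=False
        )
        rows = [
            {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "hgmd_class": v}
            for k, v in self.hgmd_table.items()
        ]
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "hgmd_class"]).to_csv(
            hgmd_path, sep="\t", index=False
        )
        tool_cols = [t for t in TOOLS if any(t in s for s in self.tool_table.values())]
        rows = []
        for k, scores in self.tool_table.items():
            row = {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3]}
            row.update({t: scores.get(t, "") for t in tool_cols})
            rows.append(row)
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", *tool_cols]).to_csv(
            tool_path, sep="\t", index=False
        )


def annotate(records: Iterable[VariantRecord], db: AnnotationDB) -> List[VariantRecord]:
    """Left-join annotations onto records; order and length preserved.

    Each output record gains an allele frequency, a curated pathogenicity
    class (``absent`` when not in the table) and the per-tool raw scores.
    """
    out: List[VariantRecord] = []
    for r in records:
        r2 = replace(r)
        k = r.key
        if k in db.freq_table:
            r2.allele_freq = db.freq_table[k]
        if k in db.hgmd_table:
            r2.hgmd = db.hgmd_table[k]
        r2.tool_scores = dict(db.tool_table.get(k, r.tool_scores))
        out.append(r2)
    return out


# ---------------------------------------------------------------------------
# Bundled reference tables


def _data_path(name: str):
    return resources.files("mendiag.data").joinpath(name)


def load_disease_category_table(path: Optional[str] = None) -> pd.DataFrame:
    """The 19 clinical disease categories of the diagnostic panel.

    The builtin table lists the 19 categories with the number of diagnosable
    Mendelian diseases per category (4,413 in total).  A user-supplied table
    must have columns ``category`` and ``n_diseases`` with unique category
    names.
    """
    if path is None:
        with resources.as_file(_data_path("disease_categories.tsv")) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if {"category", "n_diseases"} - set(df.columns):
        raise MendiagError("category table needs columns: category, n_diseases")
    if df["category"].duplicated().any():
        dups = df.loc[df["category"].duplicated(), "category"].tolist()
        raise MendiagError(f"duplicate category names: {dups}")
    if len(df) and (df["n_diseases"] < 0).any():
        raise MendiagError("disease counts must be non-negative")
    return df.reset_index(drop=True)


@dataclass
class ProbandFixture:
    """One validation proband with its known causal mutation records."""

    proband_id: str
    disease: str
    gene: str
    records: List[VariantRecord]


_PROBAND_DISEASES = {
    "P1": ("Dent Disease 1", "CLCN5"),
    "P2": ("X-Linked Ichthyosis", "STS"),
    "P3": ("Mucolipidosis II/III Alpha&Beta", "GNPTAB"),
    "P4": ("Charcot-Marie-Tooth disease", "PMP22"),
    "P5": ("Polycystic kidney disease 1", "PKD1"),
    "P6": ("Duchenne/Becker Muscular Dystrophy", "DMD"),
    "P7": ("Nephrotic Syndrome Type 2", "NPHS2"),
    "P8": ("Pseudohypoaldosteronism Type IB", "SCNN1B"),
    "P9": ("Charcot-Marie-Tooth disease", "PMP22"),
}


def table1_vcf_path() -> str:
    """Path to the bundled 9-proband validation fixture VCF (synthetic
    genomic coordinates; the cohort publishes cDNA-level notation only)."""
    with resources.as_file(_data_path("table1_probands.synthetic.vcf")) as p:
        return str(p)


def load_table1_probands() -> List[ProbandFixture]:
    """The 9 validation probands and their 11 known mutations."""
    path = table1_vcf_path()
    vf = pysam.VariantFile(path)
    by_proband: Dict[str, List[VariantRecord]] = {}
    try:
        for rec in vf:
            pid = rec.info["PROBAND"]
            for i, alt in enumerate(rec.alts or (), start=1):
                by_proband.setdefault(pid, []).append(_record_from_pysam(rec, alt, i))
    finally:
        vf.close()
    out = []
    for pid in sorted(by_proband):
        disease, gene = _PROBAND_DISEASES[pid]
        out.append(ProbandFixture(pid, disease, gene, by_proband[pid]))
    return out
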