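"""Clonotype tables, germline segment libraries and annotation tables.

The in-memory model mirrors what UMI-based TCR-beta sequencing pipelines
produce after clonotype assembly: each :class:`Clonotype` is one assembled
rearrangement (CDR3 nucleotide/amino-acid sequence, V/D/J calls, UMI count
and, when known, the number of non-template nucleotides at each junction),
and a :class:`Repertoire` is one sorted-subset sample.

Clonotype identity is the triple ``(v_gene, cdr3_nt, j_gene)`` at gene
level; allele suffixes (``*01``) are stripped on read so that V-matched
overlap between samples is well defined.  CDR3 nucleotide coordinates run
from the conserved Cys codon through the conserved Phe codon of the J
segment, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import FormatError, RecordError, ValidationError

_DNA = set("ACGT")
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def translate_cdr3(nt: str) -> str:
    """Translate a CDR3 nucleotide sequence codon by codon.

    A trailing partial codon (out-of-frame rearrangement) is rendered as a
    single ``'_'`` so that non-functional sequences keep an amino-acid
    representation; stop codons appear as ``'*'``.
    """
    nt = nt.upper()
    n_full = 3 * (len(nt) // 3)
    aa = str(Seq(nt[:n_full]).translate()) if n_full else ""
    if len(nt) != n_full:
        aa += "_"
    return aa


def normalize_gene_name(raw: str, level: str = "gene") -> str:
    """Normalize a TRB gene name to ``gene`` (allele stripped) or ``family`` level.

    ``"TRBV12-3*01"`` -> ``"TRBV12-3"`` (gene) -> ``"TRBV12"`` (family).
    Idempotent at each level.
    """
    name = raw.strip()
    if not name:
        raise ValidationError("empty gene name")
    if level not in ("gene", "family"):
        raise ValidationError(f"unknown normalization level: {level!r}")
    name = name.split("*")[0]
    if level == "family":
        name = name.split("-")[0]
    return name


@dataclass
class Clonotype:
    """One assembled TCR-beta rearrangement with its UMI abundance."""

    cdr3_nt: str
    v_gene: str
    j_gene: str
    cdr3_aa: str = ""
    d_gene: str | None = None
    umi_count: int = 1
    vd_insert_len: int | None = None
    dj_insert_len: int | None = None

    def __post_init__(self):
        self.cdr3_nt = self.cdr3_nt.upper()
        if not self.cdr3_nt:
            raise ValidationError("cdr3_nt must be non-empty")
        if self.umi_count < 1:
            raise ValidationError("umi_count must be >= 1")
        if not self.cdr3_aa:
            self.cdr3_aa = translate_cdr3(self.cdr3_nt)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.v_gene, self.cdr3_nt, self.j_gene)

    @property
    def total_insert_len(self) -> int | None:
        """Total non-template nucleotides, or None when not recorded."""
        if self.vd_insert_len is None or self.dj_insert_len is None:
            return None
        return self.vd_insert_len + self.dj_insert_len

    @property
    def functionality(self) -> str:
        """'functional', 'out_of_frame' (length not a codon multiple) or 'stop_codon'."""
        if len(self.cdr3_nt) % 3 != 0:
            return "out_of_frame"
        if "*" in self.cdr3_aa:
            return "stop_codon"
        return "functional"

    @property
    def is_functional(self) -> bool:
        return self.functionality == "functional"


@dataclass
class Repertoire:
    """A sample's clonotype collection with subset / age-group metadata."""

    sample_id: str
    clonotypes: list[Clonotype]
    subset: str | None = None
    age_group: str | None = None

    @classmethod
    def from_clonotypes(cls, sample_id, clonotypes, subset=None, age_group=None):
        """Build a repertoire, summing UMI counts of duplicate clonotype keys."""
        merged: dict[tuple, Clonotype] = {}
        for c in clonotypes:
            prev = merged.get(c.key)
            if prev is None:
                merged[c.key] = replace(c)
            else:
                prev.umi_count += c.umi_count
        return cls(sample_id, list(merged.values()), subset, age_group)

    def __len__(self) -> int:
        return len(self.clonotypes)

    @property
    def total_umis(self) -> int:
        return sum(c.umi_count for c in self.clonotypes)

    def frequencies(self) -> np.ndarray:
        counts = np.array([c.umi_count for c in self.clonotypes], dtype=float)
        return counts / counts.sum()

    def functional(self) -> "Repertoire":
        """The functional (in-frame, stop-free) sub-repertoire."""
        return Repertoire(
            self.sample_id,
            [c for c in self.clonotypes if c.is_functional],
            self.subset,
            self.age_group,
        )

    def nonfunctional(self) -> "Repertoire":
        return Repertoire(
            self.sample_id,
            [c for c in self.clonotypes if not c.is_functional],
            self.subset,
            self.age_group,
        )


@dataclass
class VSegment:
    name: str
    family: str
    nt_3prime: str  # conserved Cys codon through the segment 3' end
    cdr1_aa: str | None = None
    cdr2_aa: str | None = None

    @property
    def usable_for_germline_scoring(self) -> bool:
        return bool(self.cdr1_aa) and bool(self.cdr2_aa)


@dataclass
class DSegment:
    name: str
    nt: str


@dataclass
class JSegment:
    name: str
    nt: str
    anchor_offset: int  # 0-based offset of the conserved Phe codon within nt


@dataclass
class SegmentLibrary:
    """Germline V/D/J entries used by the simulator and germline CDR scoring."""

    v_segments: list[VSegment] = field(default_factory=list)
    d_segments: list[DSegment] = field(default_factory=list)
    j_segments: list[JSegment] = field(default_factory=list)

    def __post_init__(self):
        names = (
            [v.name for v in self.v_segments]
            + [d.name for d in self.d_segments]
            + [j.name for j in self.j_segments]
        )
        if len(names) != len(set(names)):
            raise ValidationError("segment names must be unique")
        for v in self.v_segments:
            if len(v.nt_3prime) < 3 or translate_cdr3(v.nt_3prime[:3]) != "C":
                raise ValidationError(
                    f"V segment {v.name}: nt_3prime must begin with a Cys codon"
                )
        for j in self.j_segments:
            if not 0 <= j.anchor_offset <= len(j.nt) - 3:
                raise ValidationError(
                    f"J segment {j.name}: anchor_offset outside sequence bounds"
                )
            codon = j.nt[j.anchor_offset : j.anchor_offset + 3]
            if translate_cdr3(codon) != "F":
                raise ValidationError(
                    f"J segment {j.name}: no Phe anchor codon at offset {j.anchor_offset}"
                )

    def v_by_name(self) -> dict[str, VSegment]:
        return {v.name: v for v in self.v_segments}


@dataclass
class AnnotationRecord:
    """A VDJdb-style annotation: CDR3aa + V gene + label + confidence score."""

    cdr3_aa: str
    v_gene: str
    species_or_epitope: str
    mhc_class: str | None = None
    score: int = 0

    def __post_init__(self):
        if not self.cdr3_aa:
            raise ValidationError("annotation cdr3_aa must be non-empty")
        if self.score < 0:
            raise ValidationError("annotation score must be >= 0")


# ---------------------------------------------------------------------------
# clonotype tables

_SIMPLE_COLUMNS = {
    "cdr3_nt": "cdr3_nt",
    "cdr3_aa": "cdr3_aa",
    "v_gene": "v_gene",
    "d_gene": "d_gene",
    "j_gene": "j_gene",
    "count": "count",
    "vd_insert": "vd_insert",
    "dj_insert": "dj_insert",
    "sample_id": "sample_id",
}

# Column map for common MiXCR-style export headers.  Insertion lengths are
# derived from junction reference points (VEnd/DBegin/DEnd/JBegin) when no
# explicit insert columns are present; negative gaps (P-nucleotide overlap
# conventions) are clamped to 0.
_MIXCR_COLUMNS = {
    "cloneCount": "count",
    "nSeqCDR3": "cdr3_nt",
    "aaSeqCDR3": "cdr3_aa",
    "bestVHit": "v_gene",
    "bestDHit": "d_gene",
    "bestJHit": "j_gene",
    "VEnd": "VEnd",
    "DBegin": "DBegin",
    "DEnd": "DEnd",
    "JBegin": "JBegin",
}

_MANDATORY = ("cdr3_nt", "v_gene", "j_gene", "count")


def read_clonotype_table(path, dialect: str = "simple", sample_id: str | None = None,
                         subset: str | None = None, age_group: str | None = None) -> Repertoire:
    """Read a clonotype TSV into a :class:`Repertoire`.

    Duplicate ``(v_gene, cdr3_nt, j_gene)`` keys are merged by summing their
    UMI counts.  Gene names are normalized to gene level.  Insertion lengths
    come from explicit ``vd_insert``/``dj_insert`` columns or, for the
    ``mixcr_like`` dialect, from junction reference points; when neither is
    present they remain absent (never fabricated as zero).
    """
    if dialect == "simple":
        colmap = _SIMPLE_COLUMNS
    elif dialect == "mixcr_like":
        colmap = _MIXCR_COLUMNS
    else:
        raise FormatError(f"unknown dialect: {dialect!r}")

    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns={k: v for k, v in colmap.items() if k in df.columns})
    for col in _MANDATORY:
        if col not in df.columns:
            raise FormatError(f"missing column: {col}")

    if sample_id is None:
        if "sample_id" in df.columns and df["sample_id"].notna().any():
            sample_id = str(df["sample_id"].dropna().iloc[0])
        else:
            sample_id = str(path)

    clonotypes = []
    for i, rec in enumerate(df.to_dict("records"), start=2):  # 1 = header
        try:
            count = int(float(rec["count"]))
        except (TypeError, ValueError):
            raise RecordError("unparseable count", line=i)
        if count <= 0:
            raise RecordError("non-positive count", line=i)
        vd, dj = _insert_lengths(rec)
        d_raw = rec.get("d_gene")
        d_gene = None
        if isinstance(d_raw, str) and d_raw.strip() and d_raw.strip() != ".":
            d_gene = normalize_gene_name(_first_hit(d_raw), "gene")
        aa = rec.get("cdr3_aa")
        clonotypes.append(
            Clonotype(
                cdr3_nt=rec["cdr3_nt"],
                cdr3_aa=aa if isinstance(aa, str) and aa else "",
                v_gene=normalize_gene_name(_first_hit(rec["v_gene"]), "gene"),
                d_gene=d_gene,
                j_gene=normalize_gene_name(_first_hit(rec["j_gene"]), "gene"),
                umi_count=count,
                vd_insert_len=vd,
                dj_insert_len=dj,
            )
        )
    return Repertoire.from_clonotypes(sample_id, clonotypes, subset, age_group)


def _first_hit(raw: str) -> str:
    """Take the best hit from 'TRBV7-2*01(1234),TRBV7-3*01(456)'-style fields."""
    return raw.split(",")[0].split("(")[0]


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() == "nan" or s == ".":
        return None
    return int(float(s))


def _insert_lengths(rec: dict) -> tuple[int | None, int | None]:
    vd = _opt_int(rec.get("vd_insert"))
    dj = _opt_int(rec.get("dj_insert"))
    if vd is not None or dj is not None:
        return vd, dj
    v_end = _opt_int(rec.get("VEnd"))
    d_begin = _opt_int(rec.get("DBegin"))
    d_end = _opt_int(rec.get("DEnd"))
    j_begin = _opt_int(rec.get("JBegin"))
    if v_end is None or j_begin is None or v_end < 0 or j_begin < 0:
        return None, None
    if d_begin is None or d_end is None or d_begin < 0 or d_end < 0:
        # D-less rearrangement: the single VJ insertion run is recorded on
        # the VD side, 0 on the DJ side.
        return max(j_begin - v_end, 0), 0
    return max(d_begin - v_end, 0), max(j_begin - d_end, 0)


def write_clonotype_table(rep: Repertoire, path) -> None:
    """Write a repertoire as a simple-dialect TSV (round-trips with read)."""
    rows = []
    for c in sorted(rep.clonotypes, key=lambda c: (-c.umi_count, c.cdr3_nt)):
        rows.append(
            {
                "sample_id": rep.sample_id,
                "cdr3_nt": c.cdr3_nt,
                "cdr3_aa": c.cdr3_aa,
                "v_gene": c.v_gene,
                "d_gene": c.d_gene if c.d_gene else "",
                "j_gene": c.j_gene,
                "count": c.umi_count,
                "vd_insert": "" if c.vd_insert_len is None else c.vd_insert_len,
                "dj_insert": "" if c.dj_insert_len is None else c.dj_insert_len,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# segment library

def read_segment_library(path) -> SegmentLibrary:
    """Read a segment-library TSV (columns: class, name, family, cdr1_aa,
    cdr2_aa, sequence, anchor_offset)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("class", "name", "sequence"):
        if col not in df.columns:
            raise FormatError(f"missing column: {col}")
    vs, ds, js = [], [], []
    for i, rec in enumerate(df.to_dict("records"), start=2):
        cls = str(rec["class"]).strip().upper()
        name = str(rec["name"]).strip()
        seq = str(rec["sequence"]).strip().upper()
        if cls == "V":
            fam = rec.get("family")
            fam = (
                str(fam).strip()
                if isinstance(fam, str) and str(fam).strip()
                else normalize_gene_name(name, "family")
            )
            cdr1 = rec.get("cdr1_aa")
            cdr2 = rec.get("cdr2_aa")
            vs.append(
                VSegment(
                    name=name,
                    family=fam,
                    nt_3prime=seq,
                    cdr1_aa=str(cdr1).strip() if isinstance(cdr1, str) and str(cdr1).strip() else None,
                    cdr2_aa=str(cdr2).strip() if isinstance(cdr2, str) and str(cdr2).strip() else None,
                )
            )
        elif cls == "D":
            ds.append(DSegment(name=name, nt=seq))
        elif cls == "J":
            anchor = _opt_int(rec.get("anchor_offset"))
            if anchor is None:
                raise RecordError(f"J segment {name}: missing anchor_offset", line=i)
            js.append(JSegment(name=name, nt=seq, anchor_offset=anchor))
        else:
            raise RecordError(f"unknown segment class {cls!r}", line=i)
    return SegmentLibrary(vs, ds, js)


def write_segment_library(lib: SegmentLibrary, path) -> None:
    rows = []
    for v in lib.v_segments:
        rows.append({"class": "V", "name": v.name, "family": v.family,
                     "cdr1_aa": v.cdr1_aa or "", "cdr2_aa": v.cdr2_aa or "",
                     "sequence": v.nt_3prime, "anchor_offset": ""})
    for d in lib.d_segments:
        rows.append({"class": "D", "name": d.name, "family": "", "cdr1_aa": "",
                     "cdr2_aa": "", "sequence": d.nt, "anchor_offset": ""})
    for j in lib.j_segments:
        rows.append({"class": "J", "name": j.name, "family": "", "cdr1_aa": "",
                     "cdr2_aa": "", "sequence": j.nt, "anchor_offset": j.anchor_offset})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation tables (VDJdb-style)

_ANNOT_ALIASES = {
    "cdr3": "cdr3_aa",
    "cdr3_aa": "cdr3_aa",
    "cdr3.aa": "cdr3_aa",
    "v.segm": "v_gene",
    "v": "v_gene",
    "v_gene": "v_gene",
    "species": "label",
    "antigen.species": "label",
    "antigen": "label",
    "label": "label",
    "mhc.class": "mhc_class",
    "mhc_class": "mhc_class",
    "vdjdb.score": "score",
    "score": "score",
}

_MHC_VALUES = {"I": "I", "MHCI": "I", "1": "I", "II": "II", "MHCII": "II", "2": "II"}


def read_annotation_table(path, min_score: int = 1, mhc_class: str | None = None) -> list[AnnotationRecord]:
    """Read a VDJdb-style annotation TSV, keeping records with
    ``score >= min_score`` (and, optionally, a given MHC class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns={c: _ANNOT_ALIASES[c.lower()] for c in df.columns
                            if c.lower() in _ANNOT_ALIASES})
    for col in ("cdr3_aa", "v_gene", "score"):
        if col not in df.columns:
            raise FormatError(f"missing column: {col}")
    records = []
    for i, rec in enumerate(df.to_dict("records"), start=2):
        try:
            score = int(float(rec["score"]))
        except (TypeError, ValueError):
            raise RecordError("unparseable score", line=i)
        mhc_raw = rec.get("mhc_class")
        mhc = _MHC_VALUES.get(str(mhc_raw).strip().upper()) if isinstance(mhc_raw, str) else None
        if score < min_score:
            continue
        if mhc_class is not None and mhc != mhc_class:
            continue
        records.append(
            AnnotationRecord(
                cdr3_aa=str(rec["cdr3_aa"]).strip(),
                v_gene=normalize_gene_name(str(rec["v_gene"]), "gene"),
                species_or_epitope=str(rec.get("label", "")).strip() or "unknown",
                mhc_class=mhc,
                score=score,
            )
        )
    return records
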