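"""Physicochemical CDR profiling: Kidera factors and binding-strength scores.

Kidera factors are ten orthogonal descriptors per amino acid distilled from
188 physical properties (Kidera et al., J. Protein Chem. 4:23-55, 1985);
the table ships as a packaged text fixture and is never fetched at runtime.
Profiles are computed on a central CDR3 window (default five residues, the
part of the loop most likely to contact peptide) and averaged over
clonotypes with either UMI-frequency or unique-clonotype weighting.

The binding-strength score counts residues from the strongly interacting
set {L, F, I, M, V, W, C, Y} — a proxy for van der Waals / hydrophobic
contact potential — in a CDR window: the central CDR3 window, or the
germline CDR1/CDR2 of the clonotype's V gene.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyProfileError, ValidationError
from .io import Repertoire, SegmentLibrary
from .features import _weights

STRONG_RESIDUES = frozenset("LFIMVWCY")
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def load_kidera_table() -> pd.DataFrame:
    """The packaged 20x10 Kidera factor table (rows: amino acids)."""
    ref = resources.files("repshape.data") / "kidera_factors.tsv"
    with ref.open("rb") as fh:
        raw = fh.read()
    df = pd.read_csv(pd.io.common.BytesIO(raw), sep="\t", index_col=0)
    if df.shape != (20, 10):
        raise ValidationError("kidera table must be 20 amino acids x 10 factors")
    return df


def kidera_table_checksum() -> str:
    """SHA-256 of the packaged Kidera fixture (for provenance pinning)."""
    ref = resources.files("repshape.data") / "kidera_factors.tsv"
    with ref.open("rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def load_default_library() -> SegmentLibrary:
    """The packaged synthetic TRB segment library.

    Sequences are synthetic stand-ins shaped like human TRB segments (Cys
    anchors, realistic lengths, family structure); they are not IMGT
    germline sequences.
    """
    from .io import read_segment_library

    ref = resources.files("repshape.data") / "synthetic_trb_library.tsv"
    with resources.as_file(ref) as path:
        return read_segment_library(path)


@dataclass
class StrengthConfig:
    """Configuration for binding-strength scoring."""

    strong_residues: frozenset = STRONG_RESIDUES
    cdr3_window: int = 5
    score_kind: str = "count"  # or "fraction"
    weighting: str = "umi"  # or "clonotype"
    cdr_trim: int = 0  # residues trimmed from each end of germline CDR1/CDR2

    def __post_init__(self):
        if self.cdr3_window < 1:
            raise ValidationError("cdr3_window must be >= 1")
        if not self.strong_residues <= set(AA_ORDER):
            raise ValidationError("strong_residues must be standard amino acids")
        if self.score_kind not in ("count", "fraction"):
            raise ValidationError(f"unknown score_kind: {self.score_kind!r}")
        if self.cdr_trim < 0:
            raise ValidationError("cdr_trim must be >= 0")

    def window_score(self, window: str) -> float:
        hits = sum(1 for a in window if a in self.strong_residues)
        return hits / len(window) if self.score_kind == "fraction" else float(hits)


def central_window(aa: str, w: int) -> str | None:
    """The ``w`` central residues of ``aa`` (start = floor((len-w)/2)), or
    None when the sequence is shorter than the window."""
    if len(aa) < w:
        return None
    start = (len(aa) - w) // 2
    return aa[start : start + w]


def _eligible(rep: Repertoire, w: int):
    """Functional clonotypes whose CDR3aa covers the window, with their windows."""
    out = []
    for c in rep.functional().clonotypes:
        win = central_window(c.cdr3_aa, w)
        if win is not None and set(win) <= set(AA_ORDER):
            out.append((c, win))
    return out


def kidera_profile(rep: Repertoire, table: pd.DataFrame | None = None,
                   w: int = 5, weighting: str = "umi") -> pd.Series:
    """Mean Kidera factor vector over the central CDR3 windows of a repertoire.

    Each factor is first averaged over the window residues of a clonotype,
    then averaged over clonotypes with the chosen weighting.
    """
    if table is None:
        table = load_kidera_table()
    eligible = _eligible(rep, w)
    if not eligible:
        raise EmptyProfileError("no functional clonotype covers the CDR3 window")
    clonotypes = [c for c, _ in eligible]
    weights = _weights(clonotypes, weighting)
    mat = np.array([table.loc[list(win)].mean(axis=0).to_numpy() for _, win in eligible])
    return pd.Series(weights @ mat, index=table.columns)


def strength_score(rep: Repertoire, cfg: StrengthConfig, region: str,
                   library: SegmentLibrary | None = None) -> float:
    """Weighted mean binding-strength score over a repertoire for one CDR.

    ``region`` is CDR3 (central window of each clonotype's CDR3aa) or
    CDR1/CDR2 (germline CDR of the clonotype's V gene, optionally trimmed).
    Clonotypes whose V gene lacks germline CDR data are excluded with a
    warning.
    """
    if region == "CDR3":
        eligible = _eligible(rep, cfg.cdr3_window)
        if not eligible:
            raise EmptyProfileError("no eligible clonotype for CDR3 scoring")
        clonotypes = [c for c, _ in eligible]
        scores = np.array([cfg.window_score(win) for _, win in eligible])
    elif region in ("CDR1", "CDR2"):
        if library is None:
            raise ConfigurationError(f"{region} scoring requires a segment library")
        attr = "cdr1_aa" if region == "CDR1" else "cdr2_aa"
        vmap = {v.name: getattr(v, attr) for v in library.v_segments if getattr(v, attr)}
        clonotypes, scores, skipped = [], [], 0
        for c in rep.functional().clonotypes:
            cdr = vmap.get(c.v_gene)
            if cdr is None:
                skipped += 1
                continue
            if cfg.cdr_trim:
                cdr = cdr[cfg.cdr_trim : len(cdr) - cfg.cdr_trim]
            clonotypes.append(c)
            scores.append(cfg.window_score(cdr))
        if skipped:
            warnings.warn(
                f"{skipped} clonotypes excluded from {region} scoring "
                f"(V gene missing germline CDR data)", stacklevel=2
            )
        if not clonotypes:
            raise EmptyProfileError(f"no clonotype with germline {region} data")
        scores = np.array(scores)
    else:
        raise ValidationError(f"unknown region: {region!r}")
    weights = _weights(clonotypes, cfg.weighting)
    return float(weights @ scores)


def residue_frequencies(rep: Repertoire, w: int = 5, weighting: str = "umi") -> pd.Series:
    """Weighted frequency of each amino acid over all central-window
    positions of eligible functional clonotypes (sums to 1)."""
    eligible = _eligible(rep, w)
    if not eligible:
        raise EmptyProfileError("no eligible clonotype")
    clonotypes = [c for c, _ in eligible]
    weights = _weights(clonotypes, weighting)
    freq = pd.Series(0.0, index=list(AA_ORDER))
    for (c, win), wt in zip(eligible, weights):
        for a in win:
            freq[a] += wt / len(win)
    return freq


def length_match_downsample(reps: list[Repertoire], seed: int) -> list[Repertoire]:
    """Downsample functional clonotypes so all repertoires share the same
    CDR3aa length histogram (per-length minimum envelope across samples)."""
    if len(reps) < 2:
        raise ValidationError("need at least 2 repertoires")
    rng = np.random.default_rng(seed)
    by_len: list[dict[int, list]] = []
    for rep in reps:
        groups: dict[int, list] = {}
        for c in rep.functional().clonotypes:
            groups.setdefault(len(c.cdr3_aa), []).append(c)
        by_len.append(groups)
    lengths = set.union(*(set(g) for g in by_len)) if by_len else set()
    envelope = {
        length: min(len(g.get(length, ())) for g in by_len) for length in lengths
    }
    out = []
    for rep, groups in zip(reps, by_len):
        kept = []
        for length in sorted(envelope):
            take = envelope[length]
            if take == 0:
                continue
            pool = sorted(groups[length], key=lambda c: c.key)
            idx = rng.choice(len(pool), size=take, replace=False)
            kept.extend(pool[i] for i in sorted(idx))
        out.append(Repertoire(rep.sample_id, kept, rep.subset, rep.age_group))
    return out
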