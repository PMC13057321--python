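"""Per-repertoire summary statistics.

Covers the basic repertoire-quality panel: the functionality partition
(out-of-frame / stop-codon products versus productive rearrangements),
CDR3 nucleotide length, total non-template insert size, zero-insertion
frequency, convergence (nucleotide-to-amino-acid redundancy among the most
abundant clonotypes), UMI downsampling to a fixed depth, and diversity
indices (observed diversity, normalized Shannon-Wiener).

Length/insert/zero-insert statistics are computed on functional clonotypes
by default; each supports either unique-clonotype (unweighted) or
UMI-frequency weighting, because published repertoire summaries rarely
state which of the two they use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyPartitionError,
    InsufficientDepthError,
    UndefinedFeatureError,
    ValidationError,
)
from .io import Clonotype, Repertoire

DEFAULT_CONVERGENCE_TOP_N = 3000


@dataclass
class RepertoireSummary:
    """One row of a per-sample feature table (fields None when not computed)."""

    sample_id: str
    pct_nonfunctional_clonotypes: float | None = None
    pct_nonfunctional_umis: float | None = None
    mean_cdr3_nt_length: float | None = None
    mean_insert_size: float | None = None
    zero_insert_freq: float | None = None
    convergence: float | None = None
    observed_diversity: int | None = None
    normalized_shannon: float | None = None


def classify_functionality(c: Clonotype) -> str:
    """'out_of_frame' when the CDR3 nt length is not a codon multiple, else
    'stop_codon' when the translation contains '*', else 'functional'."""
    return c.functionality


def nonfunctional_fractions(rep: Repertoire) -> tuple[float, float]:
    """(fraction of non-functional clonotypes, fraction of non-functional UMIs)."""
    if not rep.clonotypes:
        raise EmptyPartitionError("repertoire is empty")
    nonf = [c for c in rep.clonotypes if not c.is_functional]
    by_clonotype = len(nonf) / len(rep.clonotypes)
    by_umi = sum(c.umi_count for c in nonf) / rep.total_umis
    return by_clonotype, by_umi


def _weights(clonotypes: list[Clonotype], weighting: str) -> np.ndarray:
    if weighting == "clonotype":
        w = np.ones(len(clonotypes))
    elif weighting == "umi":
        w = np.array([c.umi_count for c in clonotypes], dtype=float)
    else:
        raise ValidationError(f"unknown weighting: {weighting!r}")
    return w / w.sum()


def summary_features(rep: Repertoire, functional_only: bool = True,
                     weighting: str = "clonotype",
                     insert_features: bool = True) -> RepertoireSummary:
    """Mean CDR3 nt length, mean total insert size and zero-insert frequency.

    Raises :class:`UndefinedFeatureError` if insert statistics are requested
    but any included clonotype lacks recorded insertion lengths.
    """
    sub = rep.functional() if functional_only else rep
    if not sub.clonotypes:
        raise EmptyPartitionError(f"no clonotypes in {rep.sample_id} after filtering")
    w = _weights(sub.clonotypes, weighting)
    lengths = np.array([len(c.cdr3_nt) for c in sub.clonotypes], dtype=float)
    out = RepertoireSummary(
        sample_id=rep.sample_id,
        mean_cdr3_nt_length=float(w @ lengths),
    )
    if insert_features:
        totals = [c.total_insert_len for c in sub.clonotypes]
        if any(t is None for t in totals):
            raise UndefinedFeatureError(
                "insertion lengths absent; insert features are undefined"
            )
        totals = np.array(totals, dtype=float)
        out.mean_insert_size = float(w @ totals)
        out.zero_insert_freq = float(w @ (totals == 0))
    return out


def convergence(rep: Repertoire, top_n: int = DEFAULT_CONVERGENCE_TOP_N) -> float:
    """Distinct-nt / distinct-aa CDR3 ratio among the ``top_n`` most abundant
    functional clonotypes (ties broken by cdr3_nt for determinism)."""
    func = rep.functional().clonotypes
    if not func:
        raise EmptyPartitionError("no functional clonotypes")
    selected = sorted(func, key=lambda c: (-c.umi_count, c.cdr3_nt))[:top_n]
    n_nt = len({c.cdr3_nt for c in selected})
    n_aa = len({c.cdr3_aa for c in selected})
    return n_nt / n_aa


def downsample_umis(rep: Repertoire, n: int, seed: int) -> Repertoire:
    """Draw exactly ``n`` UMIs without replacement (multivariate
    hypergeometric); clonotypes that lose all UMIs are dropped."""
    total = rep.total_umis
    if n > total:
        raise InsufficientDepthError(
            f"requested {n} UMIs but {rep.sample_id} has only {total}"
        )
    rng = np.random.default_rng(seed)
    counts = np.array([c.umi_count for c in rep.clonotypes])
    new_counts = rng.multivariate_hypergeometric(counts, n)
    kept = []
    for c, k in zip(rep.clonotypes, new_counts):
        if k > 0:
            kept.append(Clonotype(c.cdr3_nt, c.v_gene, c.j_gene, c.cdr3_aa,
                                  c.d_gene, int(k), c.vd_insert_len, c.dj_insert_len))
    return Repertoire(rep.sample_id, kept, rep.subset, rep.age_group)


def diversity_indices(rep: Repertoire) -> tuple[int, float]:
    """(observed diversity, normalized Shannon-Wiener index).

    H = -sum f ln f over clonotype frequencies, normalized by ln(observed
    diversity); defined as 0 for a single-clonotype repertoire.
    """
    if not rep.clonotypes:
        raise EmptyPartitionError("repertoire is empty")
    s = len(rep.clonotypes)
    if s == 1:
        return 1, 0.0
    f = rep.frequencies()
    h = float(-(f * np.log(f)).sum())
    return s, h / np.log(s)


def repertoire_summary(rep: Repertoire, weighting: str = "clonotype",
                       top_n: int = DEFAULT_CONVERGENCE_TOP_N,
                       diversity_depth: int | None = None,
                       seed: int = 0,
                       insert_features: bool = True) -> RepertoireSummary:
    """Assemble the full summary row for one sample.

    Diversity indices are computed on the functional sub-repertoire, after
    downsampling to ``diversity_depth`` UMIs when given (samples below that
    depth raise :class:`InsufficientDepthError` for the caller to skip).
    """
    out = summary_features(rep, functional_only=True, weighting=weighting,
                           insert_features=insert_features)
    by_cl, by_umi = nonfunctional_fractions(rep)
    out.pct_nonfunctional_clonotypes = by_cl
    out.pct_nonfunctional_umis = by_umi
    out.convergence = convergence(rep, top_n)
    func = rep.functional()
    if diversity_depth is not None:
        func = downsample_umis(func, diversity_depth, seed)
    out.observed_diversity, out.normalized_shannon = diversity_indices(func)
    return out
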