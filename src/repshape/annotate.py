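"""Matching repertoire clonotypes against annotated TCR databases.

A repertoire clonotype matches an annotation record when the gene-level V
names are equal, the CDR3 amino-acid lengths are equal, and the Hamming
distance is at most ``max_mismatch`` (substitutions only; "1 mismatch" in
repertoire matching conventionally excludes indels).  Per annotation label
(e.g. CMV, EBV, SARS-CoV-2, HIV, autoantigen) the module reports the
matched clonotype set, its cumulative frequency, and — when a generative
model is supplied — the mean in-model generation probability of the matched
sequences next to the repertoire-wide mean, since database-matched public
clonotypes are expected to be recombination-favoured (high Pgen).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError
from .io import AnnotationRecord, Repertoire, SegmentLibrary
from .simulate import GenerativeModel, pgen_nt


@dataclass
class MatchResult:
    label: str
    matched_clonotypes: list[tuple[tuple[str, str, str], str, int]] = field(default_factory=list)
    cumulative_frequency: float = 0.0
    mean_pgen: float | None = None


def _hamming_within(a: str, b: str, limit: int) -> int | None:
    """Hamming distance if <= limit, else None (sequences of equal length)."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return None
    return d


def match_clonotypes(rep: Repertoire, annotations: list[AnnotationRecord],
                     max_mismatch: int = 1) -> dict[str, MatchResult]:
    """Match functional clonotypes against annotations, grouped by label.

    A clonotype counts once per label even with multiple annotation hits
    (the best — lowest — mismatch count is recorded); annotation records
    without a V call are skipped.  Cumulative frequency is taken within the
    functional sub-repertoire.
    """
    func = rep.functional().clonotypes
    total = sum(c.umi_count for c in func) or 1
    # bucket clonotypes by (V gene, CDR3aa length): the length gate is exact
    buckets: dict[tuple[str, int], list] = {}
    for c in func:
        buckets.setdefault((c.v_gene, len(c.cdr3_aa)), []).append(c)

    results: dict[str, MatchResult] = {}
    best: dict[str, dict[tuple, tuple[int, str]]] = {}
    for ann in annotations:
        if not ann.v_gene:
            continue
        label = ann.species_or_epitope
        results.setdefault(label, MatchResult(label))
        store = best.setdefault(label, {})
        for c in buckets.get((ann.v_gene, len(ann.cdr3_aa)), ()):
            d = _hamming_within(c.cdr3_aa, ann.cdr3_aa, max_mismatch)
            if d is None:
                continue
            prev = store.get(c.key)
            if prev is None or d < prev[0]:
                store[c.key] = (d, ann.cdr3_aa)

    by_key = {c.key: c for c in func}
    for label, store in best.items():
        res = results[label]
        for key, (d, ann_aa) in sorted(store.items()):
            res.matched_clonotypes.append((key, ann_aa, d))
            res.cumulative_frequency += by_key[key].umi_count / total
    return results


def annotated_profile(rep: Repertoire, annotations: list[AnnotationRecord],
                      model: GenerativeModel | None = None,
                      library: SegmentLibrary | None = None,
                      max_mismatch: int = 1) -> pd.DataFrame:
    """Per-label match table with cumulative frequencies and mean Pgen.

    Columns: label, n_matched, cumulative_frequency, mean_pgen (None when no
    model given or no matches), repertoire_mean_pgen (same for all rows).
    """
    if model is not None and library is None:
        raise ConfigurationError("a segment library is required to compute pgen")
    matches = match_clonotypes(rep, annotations, max_mismatch)

    pgen_cache: dict[str, float] = {}

    def pgen(nt: str) -> float:
        if nt not in pgen_cache:
            pgen_cache[nt] = pgen_nt(model, library, nt)
        return pgen_cache[nt]

    rep_mean = None
    if model is not None:
        func = rep.functional().clonotypes
        if func:
            rep_mean = sum(pgen(c.cdr3_nt) for c in func) / len(func)

    rows = []
    for label in sorted(matches):
        res = matches[label]
        mean_pgen = None
        if model is not None and res.matched_clonotypes:
            nts = [key[1] for key, _, _ in res.matched_clonotypes]
            mean_pgen = sum(pgen(nt) for nt in nts) / len(nts)
            res.mean_pgen = mean_pgen
        rows.append(
            {
                "label": label,
                "n_matched": len(res.matched_clonotypes),
                "cumulative_frequency": res.cumulative_frequency,
                "mean_pgen": mean_pgen,
                "repertoire_mean_pgen": rep_mean,
            }
        )
    return pd.DataFrame(rows)
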