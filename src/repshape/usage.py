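"""TRBV usage profiles, family-level CDR2 strength, and depletion analysis.

V usage is reported at gene or family level, over the functional or
non-functional partition, with clonotype or UMI weighting.  Families are
ordered by the predicted binding strength of their germline CDR2 (mean over
member genes of the strong-residue count), which is the natural sort order
for age-trend displays.  The depletion analysis removes chosen V families,
renormalizes, and re-scores CDR2 strength, to test how much of a
between-group strength difference is carried by those families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyPartitionError, ValidationError
from .io import Repertoire, SegmentLibrary, normalize_gene_name
from .physchem import StrengthConfig, strength_score


@dataclass
class UsageProfile:
    sample_id: str
    level: str
    weighting: str
    partition: str
    fractions: pd.Series  # sums to 1

    def __post_init__(self):
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValidationError("usage fractions must sum to 1")


def v_usage(rep: Repertoire, level: str = "family", weighting: str = "umi",
            partition: str = "functional") -> UsageProfile:
    """Normalized V-segment usage over the selected functionality partition."""
    if partition == "functional":
        clonotypes = rep.functional().clonotypes
    elif partition == "nonfunctional":
        clonotypes = rep.nonfunctional().clonotypes
    elif partition == "all":
        clonotypes = rep.clonotypes
    else:
        raise ValidationError(f"unknown partition: {partition!r}")
    if not clonotypes:
        raise EmptyPartitionError(f"no clonotypes in partition {partition!r}")
    if weighting == "umi":
        weights = np.array([c.umi_count for c in clonotypes], dtype=float)
    elif weighting == "clonotype":
        weights = np.ones(len(clonotypes))
    else:
        raise ValidationError(f"unknown weighting: {weighting!r}")
    weights /= weights.sum()
    names = [normalize_gene_name(c.v_gene, level) for c in clonotypes]
    fractions = pd.Series(weights).groupby(pd.Series(names)).sum().sort_index()
    return UsageProfile(rep.sample_id, level, weighting, partition, fractions)


def family_cdr2_strength(library: SegmentLibrary, cfg: StrengthConfig | None = None
                         ) -> pd.Series:
    """Per-family mean germline CDR2 strength (unweighted over member genes);
    families without CDR2 data are excluded.  Sorted ascending: this is the
    display order for usage outputs."""
    cfg = cfg or StrengthConfig()
    scores: dict[str, list[float]] = {}
    for v in library.v_segments:
        if not v.cdr2_aa:
            continue
        cdr = v.cdr2_aa
        if cfg.cdr_trim:
            cdr = cdr[cfg.cdr_trim : len(cdr) - cfg.cdr_trim]
        scores.setdefault(v.family, []).append(cfg.window_score(cdr))
    return pd.Series({fam: float(np.mean(vals)) for fam, vals in scores.items()}
                     ).sort_values(kind="stable")


def _deplete(rep: Repertoire, families: set[str]) -> Repertoire:
    kept = [c for c in rep.clonotypes
            if normalize_gene_name(c.v_gene, "family") not in families]
    return Repertoire(rep.sample_id, kept, rep.subset, rep.age_group)


def deplete_and_rescore(reps: list[Repertoire], families_to_remove: set[str],
                        cfg: StrengthConfig | None = None,
                        library: SegmentLibrary | None = None,
                        groups: list[str] | None = None
                        ) -> tuple[pd.DataFrame, dict[str, float] | None]:
    """CDR2 strength per sample before and after removing V families.

    Samples whose repertoire is fully depleted are flagged and excluded from
    the paired comparison.  When ``groups`` labels are given, the spread of
    group-mean strengths (max minus min group mean) is reported before and
    after depletion; the spread shrinking toward 0 indicates the removed
    families carried the between-group difference.
    """
    cfg = cfg or StrengthConfig()
    if library is None:
        raise ValidationError("a segment library is required for CDR2 scoring")
    families = {normalize_gene_name(f, "family") for f in families_to_remove}
    rows = []
    for i, rep in enumerate(reps):
        before = strength_score(rep, cfg, "CDR2", library)
        depleted = _deplete(rep, families)
        fully = not depleted.functional().clonotypes
        after = None if fully else strength_score(depleted, cfg, "CDR2", library)
        rows.append(
            {
                "sample_id": rep.sample_id,
                "group": groups[i] if groups is not None else rep.age_group,
                "before": before,
                "after": after,
                "fully_depleted": fully,
            }
        )
    df = pd.DataFrame(rows)
    spread = None
    if groups is not None or any(r["group"] for r in rows):
        usable = df[~df.fully_depleted]
        if usable["group"].notna().any():
            gb_before = usable.groupby("group")["before"].mean()
            gb_after = usable.groupby("group")["after"].mean()
            spread = {
                "before": float(gb_before.max() - gb_before.min()),
                "after": float(gb_after.max() - gb_after.min()),
            }
    return df, spread
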