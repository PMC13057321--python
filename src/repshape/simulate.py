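"""V(D)J recombination simulator with exact in-model generation probability.

The generative model is deliberately simple and fully explicit, so that the
probability of any CDR3 nucleotide sequence can be computed exactly by
summing over every recombination scenario consistent with it:

1. draw V, D and J segments from categorical weights;
2. trim each junction-facing end by a truncated-geometric number of
   nucleotides (parameter ``deletion_q``, capped by ``max_deletion`` and by
   the available nucleotides; the conserved Cys codon of V and everything
   from the J Phe-anchor onward are never deleted);
3. insert non-template nucleotides at the V-D and D-J junctions (or the
   single V-J junction when the D segment is skipped).  Each insertion run
   has length 0 with probability ``insertion_zero_prob`` (the TdT-activity
   dial: fetal-like repertoires have a high zero probability) and otherwise
   a shifted-geometric length; inserted bases are i.i.d. from
   ``nt_composition``.

Clone sizes are log-normal; observed UMI counts are a multinomial sample
over the simulated rearrangements, which reproduces the heavy-tailed clone
size distributions of UMI-counted naive-subset repertoires.

``pgen_nt`` sums scenario probabilities over all (V, D, J, deletion,
insertion) decompositions of a query sequence via prefix/suffix split
points; on toy libraries this is exactly checkable against brute-force
enumeration, and the total probability over all generable sequences is 1.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ParameterError, ValidationError
from .io import Clonotype, Repertoire, SegmentLibrary, translate_cdr3

_DNA = "ACGT"

# Preset insertion-activity profiles.  The zero-insertion probability is the
# single interpretable dial for TdT activity: highest before the
# developmental onset of TdT expression, lowest in adults.
PRESETS = {
    "preterm_like": {"insertion_zero_prob": 0.45},
    "term_like": {"insertion_zero_prob": 0.15},
    "adult_like": {"insertion_zero_prob": 0.05},
}

_PRESET_AGE_GROUP = {"preterm_like": "preterm", "term_like": "term", "adult_like": "adult"}

_FIELD_ALIASES = {"pi0": "insertion_zero_prob", "q": "deletion_q"}


@dataclass
class GenerativeModel:
    """Parameters of the recombination model (weights keyed by segment name)."""

    v_weights: dict[str, float]
    d_weights: dict[str, float]
    j_weights: dict[str, float]
    deletion_q: float = 0.4
    max_deletion: int = 6
    insertion_zero_prob: float = 0.15
    insertion_geom_p: float = 0.3
    nt_composition: dict[str, float] = field(
        default_factory=lambda: {b: 0.25 for b in _DNA}
    )
    clone_size_sigma: float = 1.0
    d_skip_prob: float = 0.0

    def __post_init__(self):
        for label, w in (("v", self.v_weights), ("d", self.d_weights), ("j", self.j_weights)):
            if not w:
                raise ParameterError(f"{label}_weights must be non-empty")
            total = sum(w.values())
            if any(p < 0 for p in w.values()) or abs(total - 1.0) > 1e-9:
                raise ParameterError(f"{label}_weights must be non-negative and sum to 1")
        if not 0 < self.deletion_q < 1:
            raise ParameterError("deletion_q must be in (0, 1)")
        if self.max_deletion < 0:
            raise ParameterError("max_deletion must be >= 0")
        if not 0 <= self.insertion_zero_prob <= 1:
            raise ParameterError("insertion_zero_prob must be in [0, 1]")
        if not 0 < self.insertion_geom_p < 1:
            raise ParameterError("insertion_geom_p must be in (0, 1)")
        if set(self.nt_composition) != set(_DNA):
            raise ParameterError("nt_composition must cover exactly A/C/G/T")
        if abs(sum(self.nt_composition.values()) - 1.0) > 1e-9 or any(
            p < 0 for p in self.nt_composition.values()
        ):
            raise ParameterError("nt_composition must be non-negative and sum to 1")
        if self.clone_size_sigma < 0:
            raise ParameterError("clone_size_sigma must be >= 0")
        if not 0 <= self.d_skip_prob <= 1:
            raise ParameterError("d_skip_prob must be in [0, 1]")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "v_weights": dict(self.v_weights),
            "d_weights": dict(self.d_weights),
            "j_weights": dict(self.j_weights),
            "deletion_q": self.deletion_q,
            "max_deletion": self.max_deletion,
            "insertion_zero_prob": self.insertion_zero_prob,
            "insertion_geom_p": self.insertion_geom_p,
            "nt_composition": dict(self.nt_composition),
            "clone_size_sigma": self.clone_size_sigma,
            "d_skip_prob": self.d_skip_prob,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GenerativeModel":
        return cls(**data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "GenerativeModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def insertion_length_prob(self, k: int) -> float:
        """P(insertion run length = k): zero-inflated shifted geometric."""
        if k == 0:
            return self.insertion_zero_prob
        p = self.insertion_geom_p
        return (1.0 - self.insertion_zero_prob) * p * (1.0 - p) ** (k - 1)


@dataclass
class Rearrangement:
    """One recombination scenario and its assembled CDR3."""

    v_name: str
    j_name: str
    d_name: str | None
    del_v: int
    del_d5: int
    del_d3: int
    del_j: int
    ins_vd: str
    ins_dj: str
    cdr3_nt: str
    scenario_prob: float


def build_preset_model(library: SegmentLibrary, age_profile: str,
                       overrides: dict | None = None) -> GenerativeModel:
    """A model with preset TdT-activity parameters and uniform segment weights.

    ``age_profile`` is one of ``preterm_like`` / ``term_like`` /
    ``adult_like``; ``overrides`` may replace any model field (aliases
    ``pi0`` and ``q`` are accepted).
    """
    if age_profile not in PRESETS:
        raise ParameterError(f"unknown age profile: {age_profile!r}")
    if not library.v_segments or not library.d_segments or not library.j_segments:
        raise ParameterError("segment library must contain V, D and J entries")

    def uniform(names):
        return {n: 1.0 / len(names) for n in names}

    params = {
        "v_weights": uniform([v.name for v in library.v_segments]),
        "d_weights": uniform([d.name for d in library.d_segments]),
        "j_weights": uniform([j.name for j in library.j_segments]),
    }
    params.update(PRESETS[age_profile])
    for key, value in (overrides or {}).items():
        key = _FIELD_ALIASES.get(key, key)
        if key not in GenerativeModel.__dataclass_fields__:
            raise ParameterError(f"unknown model parameter: {key!r}")
        params[key] = value
    return GenerativeModel(**params)


# ---------------------------------------------------------------------------
# deletion distributions

def _trunc_geom_pmf(q: float, cap: int) -> np.ndarray:
    """P(d) proportional to q**d on {0..cap}, renormalized."""
    w = q ** np.arange(cap + 1)
    return w / w.sum()


def _v_cap(model: GenerativeModel, v) -> int:
    # the conserved Cys codon is never deleted
    return min(model.max_deletion, len(v.nt_3prime) - 3)


def _j_cap(model: GenerativeModel, j) -> int:
    # deletions never reach the Phe anchor codon
    return min(model.max_deletion, j.anchor_offset)


# ---------------------------------------------------------------------------
# simulation

def simulate_rearrangements(model: GenerativeModel, library: SegmentLibrary,
                            n: int, seed: int | np.random.Generator) -> list[Rearrangement]:
    """Draw ``n`` independent recombination scenarios.

    Deterministic given a seed; each scenario carries its exact probability
    under the model.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    vs, ds, js = library.v_segments, library.d_segments, library.j_segments
    wv = np.array([model.v_weights[v.name] for v in vs])
    wd = np.array([model.d_weights[d.name] for d in ds])
    wj = np.array([model.j_weights[j.name] for j in js])

    vi = rng.choice(len(vs), size=n, p=wv)
    di = rng.choice(len(ds), size=n, p=wd)
    ji = rng.choice(len(js), size=n, p=wj)
    d_skipped = (
        rng.random(n) < model.d_skip_prob if model.d_skip_prob > 0 else np.zeros(n, bool)
    )

    q = model.deletion_q
    pmf_cache: dict[int, np.ndarray] = {}

    def pmf(cap: int) -> np.ndarray:
        if cap not in pmf_cache:
            pmf_cache[cap] = _trunc_geom_pmf(q, cap)
        return pmf_cache[cap]

    def sample_trunc(u: np.ndarray, cap: int) -> np.ndarray:
        return np.searchsorted(np.cumsum(pmf(cap)), u, side="right").clip(max=cap)

    del_v = np.zeros(n, dtype=int)
    u = rng.random(n)
    for k, v in enumerate(vs):
        m = vi == k
        if m.any():
            del_v[m] = sample_trunc(u[m], _v_cap(model, v))

    del_j = np.zeros(n, dtype=int)
    u = rng.random(n)
    for k, j in enumerate(js):
        m = ji == k
        if m.any():
            del_j[m] = sample_trunc(u[m], _j_cap(model, j))

    d5 = np.zeros(n, dtype=int)
    u = rng.random(n)
    for k, d in enumerate(ds):
        m = di == k
        if m.any():
            d5[m] = sample_trunc(u[m], min(model.max_deletion, len(d.nt)))
    d3 = np.zeros(n, dtype=int)
    u = rng.random(n)
    for k, d in enumerate(ds):
        for x in range(min(model.max_deletion, len(d.nt)) + 1):
            m = (di == k) & (d5 == x)
            if m.any():
                d3[m] = sample_trunc(u[m], min(model.max_deletion, len(d.nt) - x))

    # insertion run lengths: zero-inflated shifted geometric
    def ins_lengths() -> np.ndarray:
        zero = rng.random(n) < model.insertion_zero_prob
        length = rng.geometric(model.insertion_geom_p, size=n)
        length[zero] = 0
        return length

    len_vd = ins_lengths()
    len_dj = ins_lengths()
    len_dj[d_skipped] = 0  # single VJ junction when D is skipped

    comp = np.array([model.nt_composition[b] for b in _DNA])
    total_nt = int(len_vd.sum() + len_dj.sum())
    bases = rng.choice(4, size=total_nt, p=comp) if total_nt else np.empty(0, int)
    base_str = "".join(_DNA[b] for b in bases)
    offsets = np.concatenate([[0], np.cumsum(np.concatenate([len_vd, len_dj]))])

    out = []
    for i in range(n):
        v, d, j = vs[vi[i]], ds[di[i]], js[ji[i]]
        ins_vd = base_str[offsets[i] : offsets[i + 1]]
        ins_dj = base_str[offsets[n + i] : offsets[n + i + 1]]
        v_part = v.nt_3prime[: len(v.nt_3prime) - del_v[i]]
        j_part = j.nt[del_j[i] :]
        if d_skipped[i]:
            d_part = ""
            cdr3 = v_part + ins_vd + j_part
        else:
            d_part = d.nt[d5[i] : len(d.nt) - d3[i]]
            cdr3 = v_part + ins_vd + d_part + ins_dj + j_part

        prob = (
            model.v_weights[v.name]
            * model.j_weights[j.name]
            * pmf(_v_cap(model, v))[del_v[i]]
            * pmf(_j_cap(model, j))[del_j[i]]
            * model.insertion_length_prob(len(ins_vd))
        )
        for b in ins_vd + ins_dj:
            prob *= model.nt_composition[b]
        if d_skipped[i]:
            prob *= model.d_skip_prob
        else:
            cap5 = min(model.max_deletion, len(d.nt))
            prob *= (
                (1.0 - model.d_skip_prob)
                * model.d_weights[d.name]
                * pmf(cap5)[d5[i]]
                * pmf(min(model.max_deletion, len(d.nt) - d5[i]))[d3[i]]
                * model.insertion_length_prob(len(ins_dj))
            )
        out.append(
            Rearrangement(
                v_name=v.name,
                j_name=j.name,
                d_name=None if d_skipped[i] else d.name,
                del_v=int(del_v[i]),
                del_d5=0 if d_skipped[i] else int(d5[i]),
                del_d3=0 if d_skipped[i] else int(d3[i]),
                del_j=int(del_j[i]),
                ins_vd=ins_vd,
                ins_dj=ins_dj,
                cdr3_nt=cdr3,
                scenario_prob=float(prob),
            )
        )
    return out


def simulate_repertoire(model: GenerativeModel, library: SegmentLibrary,
                        n_rearrangements: int, n_umis: int, seed: int,
                        sample_id: str = "sim", subset: str | None = None,
                        age_group: str | None = None) -> Repertoire:
    """Simulate a UMI-counted repertoire.

    ``n_rearrangements`` independent scenarios receive log-normal clone
    weights; ``n_umis`` UMIs are drawn multinomially over them and identical
    ``(V, cdr3_nt, J)`` keys are collapsed.  Insertion lengths are recorded
    from the generating scenario (first-drawn scenario on key collision).
    """
    if n_umis < 1:
        raise ParameterError("n_umis must be >= 1")
    rng = np.random.default_rng(seed)
    rearrs = simulate_rearrangements(model, library, n_rearrangements, rng)
    weights = rng.lognormal(mean=0.0, sigma=model.clone_size_sigma, size=n_rearrangements) \
        if model.clone_size_sigma > 0 else np.ones(n_rearrangements)
    counts = rng.multinomial(n_umis, weights / weights.sum())

    merged: dict[tuple, Clonotype] = {}
    for r, k in zip(rearrs, counts):
        if k == 0:
            continue
        key = (r.v_name, r.cdr3_nt, r.j_name)
        prev = merged.get(key)
        if prev is None:
            merged[key] = Clonotype(
                cdr3_nt=r.cdr3_nt,
                cdr3_aa=translate_cdr3(r.cdr3_nt),
                v_gene=r.v_name,
                d_gene=r.d_name,
                j_gene=r.j_name,
                umi_count=int(k),
                vd_insert_len=len(r.ins_vd),
                dj_insert_len=len(r.ins_dj),
            )
        else:
            prev.umi_count += int(k)
    return Repertoire(sample_id, list(merged.values()), subset, age_group)


def apply_selection(rep: Repertoire, nonfunctional_share: float = 0.08,
                    seed: int = 0) -> Repertoire:
    """Model post-recombination selection against non-productive transcripts.

    Raw recombination yields roughly two thirds out-of-frame products;
    observed naive-subset mRNA repertoires carry only a small residual
    non-functional fraction.  This filter keeps all functional clonotypes
    and hypergeometrically downsamples non-functional UMIs until they make
    up at most ``nonfunctional_share`` of the total.
    """
    if not 0 <= nonfunctional_share < 1:
        raise ParameterError("nonfunctional_share must be in [0, 1)")
    func = [c for c in rep.clonotypes if c.is_functional]
    nonf = [c for c in rep.clonotypes if not c.is_functional]
    f_umis = sum(c.umi_count for c in func)
    target = int(round(nonfunctional_share / (1 - nonfunctional_share) * f_umis))
    nf_umis = sum(c.umi_count for c in nonf)
    kept = list(func)
    if nonf and nf_umis > target:
        rng = np.random.default_rng(seed)
        counts = np.array([c.umi_count for c in nonf])
        new_counts = rng.multivariate_hypergeometric(counts, target) if target > 0 else np.zeros_like(counts)
        for c, k in zip(nonf, new_counts):
            if k > 0:
                kept.append(Clonotype(c.cdr3_nt, c.v_gene, c.j_gene, c.cdr3_aa,
                                      c.d_gene, int(k), c.vd_insert_len, c.dj_insert_len))
    else:
        kept.extend(nonf)
    return Repertoire(rep.sample_id, kept, rep.subset, rep.age_group)


def simulate_cohort(library: SegmentLibrary, age_profile: str, n_samples: int,
                    n_rearrangements: int = 3000, n_umis: int = 4500,
                    seed: int = 0, subset: str = "naive_CD4",
                    overrides: dict | None = None,
                    nonfunctional_share: float | None = 0.08) -> list[Repertoire]:
    """Simulate a cohort of same-profile samples with distinct sub-seeds."""
    model = build_preset_model(library, age_profile, overrides)
    age_group = _PRESET_AGE_GROUP[age_profile]
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_samples) % (2**31)
    reps = []
    for i in range(n_samples):
        rep = simulate_repertoire(
            model, library, n_rearrangements, n_umis, int(seeds[2 * i]),
            sample_id=f"{age_profile}_{i:02d}", subset=subset, age_group=age_group,
        )
        if nonfunctional_share is not None:
            rep = apply_selection(rep, nonfunctional_share, int(seeds[2 * i + 1]))
        reps.append(rep)
    return reps


# ---------------------------------------------------------------------------
# generation probability

def pgen_nt(model: GenerativeModel, library: SegmentLibrary, cdr3_nt: str) -> float:
    """Exact in-model generation probability of a CDR3 nucleotide sequence.

    Sums the probability of every (V, D, J, deletion, insertion) scenario
    whose assembled sequence equals ``cdr3_nt``: V-prefix and J-suffix
    masses are accumulated per split point, then D placements and the two
    insertion runs (one run for D-less scenarios) are summed over the
    remaining middle segment.  Returns 0 when no scenario exists.
    """
    s = cdr3_nt.upper()
    if not s:
        raise ValidationError("cdr3_nt must be non-empty")
    if set(s) - set(_DNA):
        raise ValidationError("cdr3_nt contains characters outside ACGT")
    L = len(s)
    q = model.deletion_q

    prefixes: dict[int, float] = defaultdict(float)
    for v in library.v_segments:
        pv = model.v_weights.get(v.name, 0.0)
        if pv == 0:
            continue
        cap = _v_cap(model, v)
        pmf = _trunc_geom_pmf(q, cap)
        for dv in range(cap + 1):
            part = v.nt_3prime[: len(v.nt_3prime) - dv]
            if len(part) <= L and s.startswith(part):
                prefixes[len(part)] += pv * pmf[dv]

    suffixes: dict[int, float] = defaultdict(float)
    for j in library.j_segments:
        pj = model.j_weights.get(j.name, 0.0)
        if pj == 0:
            continue
        cap = _j_cap(model, j)
        pmf = _trunc_geom_pmf(q, cap)
        for dj in range(cap + 1):
            part = j.nt[dj:]
            if len(part) <= L and s.endswith(part):
                suffixes[len(part)] += pj * pmf[dj]

    if not prefixes or not suffixes:
        return 0.0

    comp = model.nt_composition

    def ins_prob(t: str) -> float:
        p = model.insertion_length_prob(len(t))
        for b in t:
            p *= comp[b]
        return p

    # trimmed D variants with their probabilities, grouped by resulting string
    d_variants: dict[str, float] = defaultdict(float)
    if model.d_skip_prob < 1.0:
        for d in library.d_segments:
            pd = model.d_weights.get(d.name, 0.0)
            if pd == 0:
                continue
            cap5 = min(model.max_deletion, len(d.nt))
            pmf5 = _trunc_geom_pmf(q, cap5)
            for x5 in range(cap5 + 1):
                cap3 = min(model.max_deletion, len(d.nt) - x5)
                pmf3 = _trunc_geom_pmf(q, cap3)
                for x3 in range(cap3 + 1):
                    part = d.nt[x5 : len(d.nt) - x3]
                    d_variants[part] += (1.0 - model.d_skip_prob) * pd * pmf5[x5] * pmf3[x3]

    total = 0.0
    for a, pa in prefixes.items():
        for b, pb in suffixes.items():
            if a + b > L:
                continue
            mid = s[a : L - b]
            if model.d_skip_prob > 0:
                total += pa * pb * model.d_skip_prob * ins_prob(mid)
            for d_part, pd_mass in d_variants.items():
                ld = len(d_part)
                if ld > len(mid):
                    continue
                for i in range(len(mid) - ld + 1):
                    if mid[i : i + ld] == d_part:
                        total += (
                            pa * pb * pd_mass
                            * ins_prob(mid[:i]) * ins_prob(mid[i + ld :])
                        )
    return total
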