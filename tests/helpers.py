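"""Independent oracles for the test suite.

These deliberately re-derive quantities by the most literal route possible
(plain nested loops over recombination scenario tuples, direct formula
transcriptions) so that they share no code path with the package
implementations they check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def _trunc_geom(q: float, cap: int) -> list[float]:
    w = [q**d for d in range(cap + 1)]
    s = sum(w)
    return [x / s for x in w]


def _ins_prob(model, t: str) -> float:
    if len(t) == 0:
        p = model.insertion_zero_prob
    else:
        gp = model.insertion_geom_p
        p = (1 - model.insertion_zero_prob) * gp * (1 - gp) ** (len(t) - 1)
    for b in t:
        p *= model.nt_composition[b]
    return p


def enumerate_pgen(model, library, s: str) -> float:
    """Brute-force scenario sum for one target sequence."""
    total = 0.0
    L = len(s)
    q = model.deletion_q
    for v in library.v_segments:
        capv = min(model.max_deletion, len(v.nt_3prime) - 3)
        pmfv = _trunc_geom(q, capv)
        for dv in range(capv + 1):
            vp = v.nt_3prime[: len(v.nt_3prime) - dv]
            if not s.startswith(vp):
                continue
            for j in library.j_segments:
                capj = min(model.max_deletion, j.anchor_offset)
                pmfj = _trunc_geom(q, capj)
                for dj in range(capj + 1):
                    jp = j.nt[dj:]
                    if len(vp) + len(jp) > L or not s.endswith(jp):
                        continue
                    mid = s[len(vp) : L - len(jp)]
                    base = (model.v_weights[v.name] * pmfv[dv]
                            * model.j_weights[j.name] * pmfj[dj])
                    if model.d_skip_prob > 0:
                        total += base * model.d_skip_prob * _ins_prob(model, mid)
                    for d in library.d_segments:
                        cap5 = min(model.max_deletion, len(d.nt))
                        pmf5 = _trunc_geom(q, cap5)
                        for d5 in range(cap5 + 1):
                            cap3 = min(model.max_deletion, len(d.nt) - d5)
                            pmf3 = _trunc_geom(q, cap3)
                            for d3 in range(cap3 + 1):
                                dp = d.nt[d5 : len(d.nt) - d3]
                                for i in range(len(mid) - len(dp) + 1):
                                    if mid[i : i + len(dp)] == dp:
                                        total += (
                                            base
                                            * (1 - model.d_skip_prob)
                                            * model.d_weights[d.name]
                                            * pmf5[d5] * pmf3[d3]
                                            * _ins_prob(model, mid[:i])
                                            * _ins_prob(model, mid[i + len(dp):])
                                        )
    return total


def enumerate_zero_insert_sequences(model, library) -> set[str]:
    """All sequences generable with zero insertions at both junctions."""
    seqs = set()
    for v in library.v_segments:
        for dv in range(min(model.max_deletion, len(v.nt_3prime) - 3) + 1):
            vp = v.nt_3prime[: len(v.nt_3prime) - dv]
            for d in library.d_segments:
                for d5 in range(min(model.max_deletion, len(d.nt)) + 1):
                    for d3 in range(min(model.max_deletion, len(d.nt) - d5) + 1):
                        dp = d.nt[d5 : len(d.nt) - d3]
                        for j in library.j_segments:
                            for dj in range(min(model.max_deletion, j.anchor_offset) + 1):
                                seqs.add(vp + dp + j.nt[dj:])
    return seqs


def reference_kruskal(groups) -> tuple[float, float]:
    """Hand-ranked tie-corrected Kruskal-Wallis formula."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        k = len(g)
        rbar = ranks[start : start + k].mean()
        h += k * rbar**2
        start += k
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - float((counts**3 - counts).sum()) / (n**3 - n)
    if tie == 0:
        return 0.0, 1.0
    h /= tie
    p = sps.chi2.sf(h, len(groups) - 1)
    return float(h), float(p)


def reference_dunn(groups):
    """Independent transcription of the tie-corrected Dunn z/p formulas."""
    arrays = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    means, sizes, start = [], [], 0
    for a in arrays:
        means.append(ranks[start : start + len(a)].mean())
        sizes.append(len(a))
        start += len(a)
    _, counts = np.unique(pooled, return_counts=True)
    ties = float((counts**3 - counts).sum())
    a2 = n * (n + 1) / 12.0 - ties / (12.0 * (n - 1))
    out = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            se = (a2 * (1.0 / sizes[i] + 1.0 / sizes[j])) ** 0.5
            z = (means[i] - means[j]) / se
            out.append((z, 2 * sps.norm.sf(abs(z))))
    return out


def reference_bh(pvalues):
    """Literal step-up transcription of the BH adjustment."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted
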