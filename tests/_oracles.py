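"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the nested-ANOVA oracle
works from raw sums of squares with explicit Python loops, the BH oracle
evaluates the step-up definition quadratically, and the hypergeometric
oracle enumerates the tail with exact integer binomials.
"""

from __future__ import annotations

import math

from scipy import stats


def nested_anova_oracle(scores, design):
    """Explicit-loop sums-of-squares F tests for one cluster.

    ``scores``: DataFrame (probe sets x arrays); ``design`` supplies groups
    and their arrays.  Returns dict of (F, df1, df2, p) triples.
    """
    groups = list(design.groups)
    arrays = {g: design.arrays_in(g) for g in groups}
    exons = list(scores.index)
    all_arrays = [a for g in groups for a in arrays[g]]

    y = {(a, e): float(scores.at[e, a]) for a in all_arrays for e in exons}
    n_obs = len(y)
    grand = sum(y.values()) / n_obs

    group_mean = {}
    for g in groups:
        vals = [y[(a, e)] for a in arrays[g] for e in exons]
        group_mean[g] = sum(vals) / len(vals)
    array_mean = {a: sum(y[(a, e)] for e in exons) / len(exons) for a in all_arrays}
    exon_mean = {e: sum(y[(a, e)] for a in all_arrays) / len(all_arrays) for e in exons}
    cell_mean = {}
    for g in groups:
        for e in exons:
            vals = [y[(a, e)] for a in arrays[g]]
            cell_mean[(g, e)] = sum(vals) / len(vals)

    E = len(exons)
    ss_group = E * sum(len(arrays[g]) * (group_mean[g] - grand) ** 2 for g in groups)
    ss_array = E * sum(
        (array_mean[a] - group_mean[g]) ** 2 for g in groups for a in arrays[g]
    )
    ss_exon = len(all_arrays) * sum((exon_mean[e] - grand) ** 2 for e in exons)
    ss_int = sum(
        len(arrays[g])
        * (cell_mean[(g, e)] - group_mean[g] - exon_mean[e] + grand) ** 2
        for g in groups
        for e in exons
    )
    ss_tot = sum((v - grand) ** 2 for v in y.values())
    ss_resid = ss_tot - ss_group - ss_array - ss_exon - ss_int

    df_group = len(groups) - 1
    df_array = sum(len(arrays[g]) - 1 for g in groups)
    df_exon = E - 1
    df_int = df_group * df_exon
    df_resid = df_array * df_exon

    def f_p(ss_n, df_n, ss_d, df_d):
        f = (ss_n / df_n) / (ss_d / df_d)
        return f, float(stats.f.sf(f, df_n, df_d))

    fg, pg = f_p(ss_group, df_group, ss_array, df_array)
    fe, pe = f_p(ss_exon, df_exon, ss_resid, df_resid)
    fi, pi = f_p(ss_int, df_int, ss_resid, df_resid)
    return {
        "f_group": fg, "p_group": pg,
        "f_exon": fe, "p_exon": pe,
        "f_interaction": fi, "p_interaction": pi,
    }


def bh_oracle(p):
    """Quadratic evaluation of the BH step-up definition."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    out = [0.0] * n
    for rank_pos, i in enumerate(order):
        candidates = [
            p[order[j]] * n / (j + 1) for j in range(rank_pos, n)
        ]
        out[i] = min(1.0, min(candidates))
    return out


def hypergeom_tail_oracle(a, n, A, G):
    """P(X >= a) by exact integer enumeration of the hypergeometric PMF."""
    denom = math.comb(G, n)
    total = 0
    for j in range(a, min(n, A) + 1):
        if n - j > G - A:
            continue
        total += math.comb(A, j) * math.comb(G - A, n - j)
    return total / denom
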