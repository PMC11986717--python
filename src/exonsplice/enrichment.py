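"""Gene-set overrepresentation of significant DE / AS gene lists.

Under the null, the number of significant genes falling in a term of size n
is hypergeometric.  Two p-values are computed per term and list: the normal
approximation at x = (a - n*p) / sqrt(n*p*(1-p)) with p the genome-wide
significant fraction, and the exact upper hypergeometric tail P(X >= a)
(a one-sided Fisher test).  Terms are flat sets; no GO DAG propagation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .chip_model import GENE_SET_CLASSES, GeneSetCatalog
from .errors import InputError

log = logging.getLogger(__name__)


def overrep_normal(a: int, n: int, p: float, continuity: bool = False) -> float:
    """Upper-tail normal p-value for observing >= a significant genes of n.

    The default evaluates the statistic exactly as printed,
    x = (a - n*p) / sqrt(n*p*(1-p)).  Because the count is discrete, this
    carries an irreducible error of about pmf(a)/2 near the centre of the
    distribution; ``continuity=True`` uses a - 0.5 instead, which
    approximates the exact tail P(X >= a) closely.
    """
    if n < 1:
        raise InputError("term size n must be >= 1")
    if a < 0 or a > n:
        raise InputError("need 0 <= a <= n")
    if p <= 0.0 or p >= 1.0:
        # degenerate background proportion: the count is deterministic
        return 1.0 if a <= n * p else 0.0
    point = a - 0.5 if continuity else a
    x = (point - n * p) / np.sqrt(n * p * (1.0 - p))
    return float(stats.norm.sf(x))


def overrep_exact(a: int, n: int, A: int, G: int) -> float:
    """Exact hypergeometric tail P(X >= a), X ~ Hypergeom(G, A, n).

    G genes tested in total, A of them significant, n in the term, a of the
    term's genes significant.
    """
    if not (0 <= A <= G and 0 <= n <= G):
        raise InputError("need 0 <= A, n <= G")
    if not (0 <= a <= min(n, A)):
        raise InputError("need 0 <= a <= min(n, A)")
    return float(stats.hypergeom.sf(a - 1, G, A, n))


def enrich_catalog(
    sig_de: set[str],
    sig_as: set[str],
    tested: set[str],
    catalog: GeneSetCatalog,
    alpha: float = 0.01,
    bh_column: bool = False,
) -> pd.DataFrame:
    """Score every catalog term against the DE and AS gene lists.

    Members are intersected with the tested-gene universe first; terms left
    empty are skipped.  The background proportion p is computed separately
    per list (significant/tested).  A term is flagged significant when the
    exact p-value of either list falls below ``alpha``; rows are sorted by
    the best p-value.  Raw p-values are reported; an optional BH-adjusted
    column (per class and list) can be added.
    """
    tested = set(tested)
    if not tested:
        raise InputError("empty tested-gene universe")
    sig_de = set(sig_de) & tested
    sig_as = set(sig_as) & tested
    G = len(tested)
    A_de, A_as = len(sig_de), len(sig_as)
    p_de = A_de / G
    p_as = A_as / G

    cat = catalog.intersect(tested)
    rows = []
    for _, term in cat.terms.iterrows():
        members = term["members"]
        n = len(members)
        if n == 0:
            continue
        a_de = len(members & sig_de)
        a_as = len(members & sig_as)
        rows.append(
            {
                "class": term["class"],
                "term_id": term["term_id"],
                "term_name": term["term_name"],
                "n": n,
                "a_de": a_de,
                "p_de_normal": overrep_normal(a_de, n, p_de) if A_de else 1.0,
                "p_de_exact": overrep_exact(a_de, n, A_de, G),
                "a_as": a_as,
                "p_as_normal": overrep_normal(a_as, n, p_as) if A_as else 1.0,
                "p_as_exact": overrep_exact(a_as, n, A_as, G),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "class", "term_id", "term_name", "n",
                "a_de", "p_de_normal", "p_de_exact",
                "a_as", "p_as_normal", "p_as_exact",
                "best_p", "significant",
            ]
        )
    df = pd.DataFrame(rows)
    df["best_p"] = df[["p_de_exact", "p_as_exact"]].min(axis=1)
    df["significant"] = (df["p_de_exact"] < alpha) | (df["p_as_exact"] < alpha)
    if bh_column:
        from .anova_core import bh_fdr

        for col in ("p_de_exact", "p_as_exact"):
            df[col + "_adj"] = np.nan
            for cls in df["class"].unique():
                m = df["class"] == cls
                df.loc[m, col + "_adj"] = bh_fdr(df.loc[m, col].to_numpy())
    df = df.sort_values(["class", "best_p", "term_id"], kind="mergesort").reset_index(drop=True)
    n_sig = {cls: int(df.loc[df["class"] == cls, "significant"].sum()) for cls in df["class"].unique()}
    log.info("enrichment: significant terms per class: %s", n_sig)
    return df


def render_paper_style(df: pd.DataFrame, top: int = 30) -> dict[str, str]:
    """Per-class report: ``rank  n_GE(p)  n_AS(p)  term`` for the top terms."""
    out = {}
    for cls in GENE_SET_CLASSES:
        sub = df[df["class"] == cls].head(top)
        if sub.empty:
            continue
        lines = ["rank\tNumber GE\tNumber AS\tGroup name"]
        for i, (_, r) in enumerate(sub.iterrows(), start=1):
            lines.append(
                f"{i}\t{r['a_de']} ({r['p_de_exact']:.2E})\t"
                f"{r['a_as']} ({r['p_as_exact']:.2E})\t{r['term_id']} {r['term_name']}"
            )
        out[cls] = "\n".join(lines) + "\n"
    return out
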