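"""Independent reference computations used only by the tests."""

import itertools

import numpy as np
import pandas as pd
from scipy import stats


def wilcoxon_enumeration_p(differences) -> float:
    """Exact two-sided signed-rank p by enumerating all sign patterns.

    Brute force over the 2^n equally likely sign assignments of the
    observed magnitudes; p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))).
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    ws = np.array(
        [sum(r for r, b in zip(ranks, bits) if b)
         for bits in itertools.product((0, 1), repeat=len(d))]
    )
    lower = np.mean(ws <= w)
    upper = np.mean(ws >= w)
    return min(1.0, 2.0 * min(lower, upper))


def icc_a1_pingouin(Y: np.ndarray) -> float:
    """Two-way random, absolute-agreement, single-measure ICC via pingouin."""
    import pingouin as pg

    n, k = Y.shape
    df = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "y": Y.ravel(),
        }
    )
    table = pg.intraclass_corr(df, "targets", "raters", "y").set_index("Type")
    return float(table.loc["ICC(A,1)", "ICC"])


def spearman_rank_then_pearson(x, y) -> float:
    """Rank (mean ranks for ties) then plain Pearson correlation."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])
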