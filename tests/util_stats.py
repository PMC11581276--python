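"""Shared statistical helpers for the test suite (oracles stay in tests)."""

import numpy as np
from scipy import stats


def two_sample_count_chi2(x, y, min_expected=5.0):
    """p-value of a two-sample chi-square test on integer count samples.

    Bins are pooled from both samples and merged outward until every
    expected cell count reaches ``min_expected``.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    hi = int(max(x.max(initial=0), y.max(initial=0)))
    fx = np.bincount(x, minlength=hi + 1).astype(float)
    fy = np.bincount(y, minlength=hi + 1).astype(float)
    total = fx + fy
    # greedy merge of adjacent bins until all pooled cells are big enough
    edges = [0]
    acc = 0.0
    for k in range(hi + 1):
        acc += total[k]
        if acc >= 2 * min_expected:
            edges.append(k + 1)
            acc = 0.0
    if acc > 0:
        if len(edges) > 1:
            edges[-1] = hi + 1
        else:
            edges.append(hi + 1)
    ox = np.array([fx[a:b].sum() for a, b in zip(edges[:-1], edges[1:])])
    oy = np.array([fy[a:b].sum() for a, b in zip(edges[:-1], edges[1:])])
    keep = (ox + oy) > 0
    table = np.stack([ox[keep], oy[keep]])
    if table.shape[1] < 2:
        return 1.0
    return float(stats.chi2_contingency(table)[1])


def tv_distance(x, y):
    """Total-variation distance between two integer samples' empirical pmfs."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    hi = int(max(x.max(initial=0), y.max(initial=0)))
    px = np.bincount(x, minlength=hi + 1) / len(x)
    py = np.bincount(y, minlength=hi + 1) / len(y)
    return float(0.5 * np.abs(px - py).sum())


def tv_against_pmf(x, pmf):
    """TV distance between a sample and an exact pmf on 0..len(pmf)-1."""
    x = np.asarray(x, dtype=np.int64)
    hi = max(int(x.max(initial=0)), len(pmf) - 1)
    px = np.bincount(x, minlength=hi + 1) / len(x)
    q = np.zeros(hi + 1)
    q[:len(pmf)] = pmf
    return float(0.5 * np.abs(px - q).sum())


def poisson_gof_p(counts, mean, min_expected=5.0):
    """Chi-square GoF p-value of counts against Poisson(mean)."""
    counts = np.asarray(counts, dtype=np.int64)
    lo = int(stats.poisson.ppf(1e-4, mean))
    hi = int(stats.poisson.ppf(1 - 1e-4, mean))
    ks = np.arange(lo, hi + 1)
    probs = stats.poisson.pmf(ks, mean)
    probs = np.concatenate(([stats.poisson.cdf(lo - 1, mean)], probs,
                            [stats.poisson.sf(hi, mean)]))
    obs = np.concatenate(([np.sum(counts < lo)],
                          [np.sum(counts == k) for k in ks],
                          [np.sum(counts > hi)])).astype(float)
    exp = probs * len(counts)
    # merge small-expectation cells into neighbours
    o_merged, e_merged = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(obs, exp):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            o_merged.append(o_acc)
            e_merged.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0 and e_merged:
        o_merged[-1] += o_acc
        e_merged[-1] += e_acc
    stat = float((((np.array(o_merged) - np.array(e_merged)) ** 2)
                  / np.array(e_merged)).sum())
    return float(stats.chi2.sf(stat, len(e_merged) - 1))
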