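"""Independent brute-force oracles used to check the vectorized code paths.

Everything here is deliberately naive: plain Python loops, stdlib math and
exhaustive enumeration. Keep it that way — the value of these oracles is
their independence from the implementations they check.
"""
import itertools
import math
import statistics

from scipy.stats import rankdata


def m_value(b, eps=0.001):
    b = min(max(b, eps), 1 - eps)
    return math.log2(b / (1 - b))


def brute_force_dm(beta_df, sample, controls, k=3.0, delta=0.2, eps=0.001):
    """Per-unit dm status computed one unit at a time, no vectorization.

    Returns {unit: (delta_beta, delta_m, status)} for units complete in all
    controls and the sample.
    """
    out = {}
    for unit in beta_df.index:
        cvals = [beta_df.at[unit, c] for c in controls]
        sval = beta_df.at[unit, sample]
        if any(v != v for v in cvals) or sval != sval:
            continue
        cms = [m_value(v, eps) for v in cvals]
        mean_m = sum(cms) / len(cms)
        sd_m = statistics.stdev(cms)
        med_b = statistics.median(cvals)
        dm = m_value(sval, eps) - mean_m
        db = sval - med_b
        if abs(dm) > k * sd_m and db > delta:
            status = "hyper"
        elif abs(dm) > k * sd_m and db < -delta:
            status = "hypo"
        else:
            status = "unchanged"
        out[unit] = (db, dm, status)
    return out


def cluster_oracle(starts, min_bins=2, size=500):
    """Exhaustive O(n^2) enumeration of maximal contiguous runs on one
    chromosome. Returns (clusters, isolated) as lists of start lists."""
    s = sorted(set(starts))
    n = len(s)
    clusters, isolated = [], []
    for i in range(n):
        for j in range(i, n):
            seg = s[i:j + 1]
            contiguous = all(seg[t + 1] - seg[t] == size
                             for t in range(len(seg) - 1))
            left_maximal = i == 0 or s[i] - s[i - 1] != size
            right_maximal = j == n - 1 or s[j + 1] - s[j] != size
            if contiguous and left_maximal and right_maximal:
                if len(seg) >= min_bins:
                    clusters.append(seg)
                else:
                    isolated.extend(seg)
    return clusters, isolated


def paired_wilcoxon_enum(differences, alternative="greater"):
    """Exact signed-rank p by enumerating all 2^n sign assignments.

    Valid for tie-free |d| after dropping zeros.
    """
    d = [x for x in differences if x != 0]
    ranks = rankdata([abs(x) for x in d])
    observed = sum(r for r, x in zip(ranks, d) if x > 0)
    hits = total = 0
    for signs in itertools.product((False, True), repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if alternative == "greater":
            hits += w >= observed
        elif alternative == "less":
            hits += w <= observed
        else:
            raise ValueError(alternative)
    return hits / total


def ranksum_enum_two_sided(a, b):
    """Exact two-sided rank-sum p by enumerating all label assignments.

    Tie-free inputs only. Uses the symmetric-deviation definition of the
    two-sided tail, which matches tail doubling for the (symmetric) null
    rank-sum distribution.
    """
    pooled = list(a) + list(b)
    assert len(set(pooled)) == len(pooled), "tie-free inputs only"
    ranks = rankdata(pooled)
    n1 = len(a)
    observed = sum(ranks[:n1])
    mean = n1 * (len(pooled) + 1) / 2
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        w = sum(ranks[i] for i in idx)
        total += 1
        if abs(w - mean) >= abs(observed - mean) - 1e-12:
            hits += 1
    return hits / total
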