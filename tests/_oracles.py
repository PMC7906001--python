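"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected results in the most literal way
possible (explicit scans over label lists, closed-form truncated-normal
iteration) so they share no code with the implementation they check.
"""

import numpy as np
from scipy import stats as sps


def oracle_refine_labels(labels, unit_ms, min_stable_ms, min_rapid_ms):
    """Literal application of the run-refinement rules to unit-duration
    labels.  Returns the final list of (kind, n_units) runs."""

    def group(seq):
        out = []
        for lab in seq:
            if out and out[-1][0] == lab:
                out[-1][1] += 1
            else:
                out.append([lab, 1])
        return out

    runs = group(list(labels))
    # short stable runs -> rapid, all at once on the initial grouping
    runs = [
        ["rapid", n] if (k == "stable" and n * unit_ms < min_stable_ms) else [k, n]
        for k, n in runs
    ]
    runs = group([k for k, n in runs for _ in range(n)])
    # short rapid runs with stable on both sides -> stable, all at once
    relabeled = []
    for i, (k, n) in enumerate(runs):
        flank_ok = (
            i > 0 and i < len(runs) - 1
            and runs[i - 1][0] == "stable" and runs[i + 1][0] == "stable"
        )
        if k == "rapid" and n * unit_ms < min_rapid_ms and flank_ok:
            relabeled.append(["stable", n])
        else:
            relabeled.append([k, n])
    runs = group([k for k, n in relabeled for _ in range(n)])
    return [(k, n) for k, n in runs]


def truncated_normal_fixed_point(mu, sigma, k=3.0, tol=1e-10, max_iter=10_000):
    """Fixed point of theta <- mean + k*sd of N(mu, sigma) truncated above
    at theta, computed on the true distribution via scipy.truncnorm."""
    theta = mu + k * sigma
    for _ in range(max_iter):
        alpha = (theta - mu) / sigma
        d = sps.truncnorm(-np.inf, alpha, loc=mu, scale=sigma)
        new = d.mean() + k * d.std()
        if abs(new - theta) < tol:
            return new
        theta = new
    return theta


def exact_mannwhitney_min_u_p(a, b):
    """Exact permutation probability of a min-U at least as extreme, over
    all group assignments of the pooled sample (mid-ranks for ties)."""
    import itertools

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u_obs = min(r1 - n1 * (n1 + 1) / 2, n1 * n2 - (r1 - n1 * (n1 + 1) / 2))
    hits = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        total += 1
        r = ranks[list(idx)].sum()
        u1 = r - n1 * (n1 + 1) / 2
        if min(u1, n1 * n2 - u1) <= u_obs + 1e-9:
            hits += 1
    return hits / total
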