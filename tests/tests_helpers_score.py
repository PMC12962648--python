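"""Shared helper: Cox partial-likelihood score statistic at beta = 0."""

import numpy as np


def score_statistic(time, event, covariate) -> float:
    """U(0)^2 / I(0) for a single covariate, using the package's own
    partial-likelihood kernel (the classic log-rank equivalence)."""
    import glymph.stats as gs

    X = np.asarray(covariate, float).reshape(-1, 1)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    order = np.argsort(-t, kind="stable")
    ts, es, Xs = t[order], e[order], X[order]
    ev_times = np.unique(ts[es == 1])[::-1]
    risk_idx, grp_starts, grp_sizes, ev_x_sum, ev_members = [], [], [], [], []
    for tt in ev_times:
        k = np.searchsorted(-ts, -tt, side="right")
        risk_idx.append(k - 1)
        members = np.flatnonzero((ts == tt) & (es == 1))
        grp_starts.append(members[0])
        grp_sizes.append(members.size)
        ev_members.append(members)
        ev_x_sum.append(Xs[members].sum(axis=0))
    packed = (
        Xs,
        np.asarray(risk_idx),
        grp_starts,
        grp_sizes,
        ev_x_sum,
        ev_members,
        False,
    )
    _, grad, hess = gs._partial_lik(np.zeros(1), Xs, packed)
    return float(grad[0] ** 2 / -hess[0, 0])
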