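"""Independent brute-force oracles.

Everything here is written with plain loops and direct counting, deliberately
avoiding the package's vectorized internals, so agreement between the two is
a meaningful check.
"""

def candidates_of(scores):
    return [float("-inf")] + sorted(set(scores)) + [float("inf")]


def confusion(scores, labels, tau):
    tp = sum(1 for s, y in zip(scores, labels) if s >= tau and y == 1)
    fp = sum(1 for s, y in zip(scores, labels) if s >= tau and y == 0)
    fn = sum(1 for s, y in zip(scores, labels) if s < tau and y == 1)
    tn = sum(1 for s, y in zip(scores, labels) if s < tau and y == 0)
    return tp, fp, tn, fn


def ppv(scores, labels, tau):
    tp, fp, _, _ = confusion(scores, labels, tau)
    return tp / (tp + fp) if tp + fp else None


def npv(scores, labels, tau):
    _, _, tn, fn = confusion(scores, labels, tau)
    return tn / (tn + fn) if tn + fn else None


def rule_in_boundary(scores, labels, alpha_plus):
    qualifying = [
        t for t in candidates_of(scores)
        if ppv(scores, labels, t) is not None and ppv(scores, labels, t) >= alpha_plus
    ]
    return min(qualifying) if qualifying else float("inf")


def rule_out_boundary(scores, labels, alpha_minus):
    qualifying = [
        t for t in candidates_of(scores)
        if npv(scores, labels, t) is not None and npv(scores, labels, t) >= alpha_minus
    ]
    return max(qualifying) if qualifying else float("-inf")


def partition_boundaries(scores, labels, alpha_plus, alpha_minus):
    """Effective (tau_minus, tau_plus): the qualifying pair (including empty
    sentinels) minimizing the gray count, tie-broken toward the smaller
    tau_plus and then the larger tau_minus — by exhaustive pair enumeration."""
    cands = candidates_of(scores)
    lo, hi = float("-inf"), float("inf")
    q_in = {t for t in cands
            if ppv(scores, labels, t) is not None and ppv(scores, labels, t) >= alpha_plus}
    q_out = {t for t in cands
             if npv(scores, labels, t) is not None and npv(scores, labels, t) >= alpha_minus}
    best = None
    for tm in sorted(q_out | {lo}):
        for tp in sorted(q_in | {hi}):
            if tm > tp:
                continue
            gray = sum(1 for s in scores if tm <= s < tp)
            key = (gray, tp, -tm)
            if best is None or key < best[0]:
                best = (key, tm, tp)
    return best[1], best[2]


def gamma_area(scores, labels, alpha):
    """Γ from the raw boundaries at a symmetric safety level."""
    tm = rule_out_boundary(scores, labels, alpha)
    tp = rule_in_boundary(scores, labels, alpha)
    n_neg = sum(1 for y in labels if y == 0)
    n_pos = sum(1 for y in labels if y == 1)
    fpr = sum(1 for s, y in zip(scores, labels) if y == 0 and s >= tm) / n_neg
    tpr = sum(1 for s, y in zip(scores, labels) if y == 1 and s >= tp) / n_pos
    return fpr * (1.0 - tpr)


def auc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def youden(scores, labels):
    """Argmax of TPR - FPR over unique scores plus the above-max sentinel;
    ties to higher TPR, then lower threshold."""
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    best = None
    for t in candidates_of(scores)[1:]:
        tp, fp, tn, fn = confusion(scores, labels, t)
        tpr, fpr = tp / n_pos, fp / n_neg
        key = (-(tpr - fpr), -tpr, t)
        if best is None or key < best[0]:
            best = (key, t)
    return best[1]


def utility_argmax(scores, labels, u_tp, u_tn, u_fp, u_fn, u_gray):
    """Exhaustive utility maximization over all candidate pairs with the
    documented tie-break (fewest errors, fewest gray, smallest (τ⁻, τ⁺))."""
    cands = candidates_of(scores)
    best = None
    for i, tm in enumerate(cands):
        for tp_ in cands[i:]:
            n_tp = n_tn = n_fp = n_fn = n_gray = 0
            for s, y in zip(scores, labels):
                if s >= tp_:
                    n_tp, n_fp = n_tp + (y == 1), n_fp + (y == 0)
                elif s < tm:
                    n_tn, n_fn = n_tn + (y == 0), n_fn + (y == 1)
                else:
                    n_gray += 1
            u = (n_tp * u_tp + n_tn * u_tn + n_fp * u_fp + n_fn * u_fn
                 + n_gray * u_gray)
            key = (-u, n_fp + n_fn, n_gray, tm, tp_)
            if best is None or key < best[0]:
                best = (key, u, tm, tp_)
    return best[1], best[2], best[3]


def bootstrap_auc_interval(scores, labels, B, seed):
    """Independent reimplementation of the documented bootstrap recipe:
    default_rng(seed), per replicate rng.integers(0, n, n), redraw on
    single-class, percentile 2.5/97.5 of the AUC."""
    import numpy as np

    rng = np.random.default_rng(seed)
    n = len(scores)
    vals = []
    while len(vals) < B:
        idx = rng.integers(0, n, n)
        lab = [labels[i] for i in idx]
        if sum(lab) in (0, n):
            continue
        vals.append(auc([scores[i] for i in idx], lab))
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)
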