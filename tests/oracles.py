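"""Independent, deliberately naive reference implementations.

These stay loop-based and self-contained so they can serve as oracles
for the vectorised library code: a brute-force O(T^2) sample-entropy
counter, a straight-line belief-value computation, and direct
confusion-matrix rates.
"""

import math

import numpy as np


def sampen_bruteforce(x, m=2, r=0.2):
    """Sample entropy by explicit template counting (Chebyshev, no self-matches)."""
    x = list(map(float, x))
    n = len(x)
    sd = math.sqrt(sum((v - sum(x) / n) ** 2 for v in x) / n)
    if sd == 0:
        return 0.0
    tol = r * sd
    counts = []
    for length in (m, m + 1):
        n_templates = n - m  # both lengths use the first n-m templates
        c = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                if max(abs(x[i + t] - x[j + t]) for t in range(length)) <= tol:
                    c += 1
        counts.append(c)
    b_count, a_count = counts
    if a_count == 0 or b_count == 0:
        return math.inf
    return -math.log(a_count / b_count)


def belief_value_straightline(
    w, b, X_train, y_train, x, metric="mahalanobis", effect_mode="w_times_s",
    neighbor_sign="true_label", cov_shrinkage=1e-2,
):
    """Belief-value recomputed step by step with plain loops.

    Same contract as the library: neighbours are training points on the
    test point's predicted side; distances z-scored by population SD;
    Gaussian weights; probabilities from the labelled margins; mean
    effect.  Falls back to the sample's own margin probability when the
    side is empty.
    """
    w = np.asarray(w, float)
    norm = math.sqrt(float(w @ w))
    n = len(y_train)

    def raw_dist(pt):
        return (float(np.dot(w, pt)) + b) / norm

    r_x = raw_dist(x)
    side = 1 if r_x >= 0 else -1
    members = [i for i in range(n) if np.sign(raw_dist(X_train[i])) == side]
    if not members:
        return np.sign(r_x) / (1.0 + math.exp(-abs(r_x)))

    if metric == "mahalanobis":
        cov = np.cov(np.asarray(X_train, float), rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        dim = cov.shape[0]
        scale = np.trace(cov) / dim
        if scale <= 0:
            scale = 1.0
        vi = np.linalg.inv(cov + cov_shrinkage * scale * np.eye(dim))

    D = []
    for i in members:
        diff = np.asarray(x, float) - np.asarray(X_train[i], float)
        if metric == "euclidean":
            D.append(math.sqrt(float(diff @ diff)))
        elif metric == "manhattan":
            D.append(float(np.abs(diff).sum()))
        else:
            D.append(math.sqrt(max(float(diff @ vi @ diff), 0.0)))

    mu = sum(D) / len(D)
    sigma = math.sqrt(sum((d - mu) ** 2 for d in D) / len(D))
    d_prime = [0.0] * len(D) if sigma == 0 else [(d - mu) / sigma for d in D]

    effects = []
    for idx, i in enumerate(members):
        weight = math.exp(-0.5 * d_prime[idx] ** 2) / math.sqrt(2 * math.pi)
        r_i = y_train[i] * raw_dist(X_train[i])
        mag = 1.0 / (1.0 + math.exp(-abs(r_i)))
        sign = y_train[i] if neighbor_sign == "true_label" else side
        s = sign * mag
        if effect_mode == "w_times_s":
            effects.append(weight * s)
        elif effect_mode == "s":
            effects.append(s)
        else:  # "w"
            effects.append(weight * np.sign(s))
    return sum(effects) / len(effects)


def confusion_rates_direct(y_true, y_pred):
    """ACC/SEN/SPE/PPV/NPV/F1 (percent) computed straight from definitions."""
    tp = fn = tn = fp = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 1 and p == -1:
            fn += 1
        elif t == -1 and p == -1:
            tn += 1
        else:
            fp += 1
    n = tp + fn + tn + fp

    def rate(a, b):
        return None if b == 0 else 100.0 * a / b

    return {
        "acc": rate(tp + tn, n),
        "sen": rate(tp, tp + fn),
        "spe": rate(tn, tn + fp),
        "ppv": rate(tp, tp + fp),
        "npv": rate(tn, tn + fn),
        "f1": rate(2 * tp, 2 * tp + fp + fn),
    }
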