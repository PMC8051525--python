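"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions with plain loops, on
purpose sharing no code path with the package.
"""

import numpy as np


# -- ITM -------------------------------------------------------------------

def naive_mean_kappa(x, delay, fs):
    """Loop-based within-lead mean kappa with the zero-difference exclusion."""
    x = np.asarray(x, float)
    dt_ms = 1000.0 * delay / fs
    vals, excluded = [], 0
    for t in range(len(x) - delay):
        dv = abs(x[t + delay] - x[t])
        if dv == 0:
            excluded += 1
            continue
        vals.append(np.log(dv) / np.log(dt_ms))
    mean = float(np.mean(vals)) if vals else float("nan")
    return mean, len(vals), excluded


def naive_mean_itcr(src, dst, delay, eps=1e-8):
    """Loop-based between-lead mean ratio with both exclusion rules."""
    vals, excluded = [], 0
    for t in range(len(src) - delay):
        dv1 = abs(src[t + delay] - src[t])
        dv2 = abs(dst[t + delay] - dst[t])
        if dv1 == 0 or dv2 == 0 or abs(np.log(dv2)) < eps:
            excluded += 1
            continue
        vals.append(np.log(dv1) / np.log(dv2))
    mean = float(np.mean(vals)) if vals else float("nan")
    return mean, len(vals), excluded


# -- DFA -------------------------------------------------------------------

def naive_dfa_fq(x, s, q, m=1):
    """Textbook MF-DFA fluctuation function, one window at a time."""
    x = np.asarray(x, float)
    y = np.cumsum(x - x.mean())
    n = len(y)
    k = n // s
    f2 = []
    for start in list(range(0, k * s, s)) + \
            list(range(n - k * s, n - s + 1, s)):
        seg = y[start:start + s]
        t = np.arange(s)
        coef = np.polyfit(t, seg, m)
        resid = seg - np.polyval(coef, t)
        f2.append(np.mean(resid ** 2))
    f2 = np.asarray(f2)
    if q == 0:
        return float(np.exp(0.5 * np.mean(np.log(f2))))
    return float(np.mean(f2 ** (q / 2.0)) ** (1.0 / q))


# -- CART ------------------------------------------------------------------

def _ss(y):
    return float(np.sum((y - y.mean()) ** 2)) if len(y) else 0.0


def oracle_grow(X, y, minsplit=4, minbucket=1):
    """Exhaustive greedy split search; dict-based tree.

    Same conventions as the package states: midpoint thresholds, < goes
    left, ties to the lowest feature index then lowest threshold.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    node = {"n": len(y), "mean": float(y.mean()), "ss": _ss(y)}
    if len(y) < minsplit or node["ss"] <= 1e-12:
        return node
    best = None
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = (a + b) / 2.0
            mask = X[:, j] < thr
            if mask.sum() < minbucket or (~mask).sum() < minbucket:
                continue
            gain = node["ss"] - _ss(y[mask]) - _ss(y[~mask])
            if best is None or gain > best[0] + 1e-12:
                best = (gain, j, thr)
    if best is None or best[0] <= 1e-12:
        return node
    _, j, thr = best
    mask = X[:, j] < thr
    node.update(feature=j, threshold=thr,
                left=oracle_grow(X[mask], y[mask], minsplit, minbucket),
                right=oracle_grow(X[~mask], y[~mask], minsplit, minbucket))
    return node


def oracle_leaves(node):
    if "feature" not in node:
        return 1
    return oracle_leaves(node["left"]) + oracle_leaves(node["right"])


def oracle_risk(node):
    if "feature" not in node:
        return node["ss"]
    return oracle_risk(node["left"]) + oracle_risk(node["right"])


def _copy(node):
    out = dict(node)
    if "feature" in node:
        out["left"] = _copy(node["left"])
        out["right"] = _copy(node["right"])
    return out


def oracle_prune_sequence(root):
    """Weakest-link pruning enumeration: [(alpha, n_leaves, risk), ...]."""
    cur = _copy(root)
    seq = [(0.0, oracle_leaves(cur), oracle_risk(cur))]
    while "feature" in cur:
        links = []

        def visit(n):
            if "feature" not in n:
                return
            g = (n["ss"] - oracle_risk(n)) / (oracle_leaves(n) - 1)
            links.append((g, n))
            visit(n["left"])
            visit(n["right"])

        visit(cur)
        gmin = min(g for g, _ in links)
        for g, n in links:
            if g <= gmin + 1e-12 * max(1.0, abs(gmin)):
                for key in ("feature", "threshold", "left", "right"):
                    n.pop(key, None)
        seq.append((max(gmin, 0.0), oracle_leaves(cur), oracle_risk(cur)))
    return seq


def trees_match(node, oracle, feature_names):
    """Node-for-node structural equality with an oracle dict tree."""
    if not np.isclose(node.mean, oracle["mean"]):
        return False
    if node.n != oracle["n"]:
        return False
    if node.is_leaf != ("feature" not in oracle):
        return False
    if node.is_leaf:
        return True
    if node.feature != oracle["feature"]:
        return False
    if not np.isclose(node.threshold, oracle["threshold"]):
        return False
    return (trees_match(node.left, oracle["left"], feature_names)
            and trees_match(node.right, oracle["right"], feature_names))
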