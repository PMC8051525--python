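"""Regression trees with cost-complexity pruning and out-of-sample reporting.

The modeling stage fits a CART regression tree to training-epoch features
(greedy binary splitting by within-node sum-of-squares reduction, minimum
node size to split ``minsplit``), records the full weakest-link pruning
sequence, selects a complexity parameter by k-fold cross-validation with the
one-standard-error rule (smallest tree whose CV error is within one SE of
the minimum), and correlates the pruned tree's predictions on test-epoch
features with the actual cognitive subscores, reporting Pearson r and its
t-statistic t = r sqrt(n-2) / sqrt(1-r^2) with n-2 degrees of freedom.

The API follows the model/results convention: :class:`CARTRegression` is
built from a feature table and response, ``fit()`` returns
:class:`CARTResults` carrying the tree, its complexity table and the CV,
pruning, prediction and summary methods. :func:`run_method_comparison`
drives the whole train -> prune -> predict -> correlate loop over a set of
subscores and returns a :class:`CorrelationReport`.

Conventions pinned for determinism: thresholds sit at midpoints of adjacent
distinct feature values; a row with feature value < threshold goes left,
>= threshold goes right; split ties are broken by lower feature index, then
lower threshold; complexity is expressed relative to the root risk
(cp = alpha / SS_root, as in rpart).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ScoreTable

_TOL = 1e-12


class UndefinedCorrelationWarning(UserWarning):
    """Pearson correlation undefined (a constant vector); reported as NaN."""


# ---------------------------------------------------------------------------
# tree structure

@dataclass
class TreeNode:
    """One node of a binary regression tree."""

    n: int                      # training rows reaching the node
    mean: float                 # mean response -> leaf prediction
    ss: float                   # within-node sum of squared deviations
    feature: Optional[int] = None       # split feature index (None = leaf)
    threshold: Optional[float] = None   # split point; < left, >= right
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def copy(self) -> "TreeNode":
        if self.is_leaf:
            return TreeNode(self.n, self.mean, self.ss)
        return TreeNode(self.n, self.mean, self.ss, self.feature,
                        self.threshold, self.left.copy(), self.right.copy())


def _n_leaves(node: TreeNode) -> int:
    if node.is_leaf:
        return 1
    return _n_leaves(node.left) + _n_leaves(node.right)


def _risk(node: TreeNode) -> float:
    """Total SSE of the subtree (sum of leaf within-node SS)."""
    if node.is_leaf:
        return node.ss
    return _risk(node.left) + _risk(node.right)


def _best_split(X: np.ndarray, y: np.ndarray, minbucket: int):
    """Exhaustive best split of one node; ties go to the lowest feature
    index, then the lowest threshold. Returns (gain, feature, threshold)
    or None."""
    n = y.size
    ss_node = float(np.sum((y - y.mean()) ** 2))
    best = None
    for j in range(X.shape[1]):
        xj = X[:, j]
        order = np.argsort(xj, kind="stable")
        xs, ys = xj[order], y[order]
        csum = np.cumsum(ys)
        csq = np.cumsum(ys ** 2)
        total, total_sq = csum[-1], csq[-1]
        for i in range(1, n):
            if xs[i] <= xs[i - 1]:
                continue
            nl, nr = i, n - i
            if nl < minbucket or nr < minbucket:
                continue
            sl = csum[i - 1]
            ssl = csq[i - 1] - sl ** 2 / nl
            sr = total - sl
            ssr = (total_sq - csq[i - 1]) - sr ** 2 / nr
            gain = ss_node - ssl - ssr
            if best is None or gain > best[0] + _TOL:
                best = (gain, j, 0.5 * (xs[i - 1] + xs[i]))
    if best is None or best[0] <= _TOL:
        return None
    return best


def _grow(X: np.ndarray, y: np.ndarray, minsplit: int,
          minbucket: int) -> TreeNode:
    node = TreeNode(n=y.size, mean=float(y.mean()),
                    ss=float(np.sum((y - y.mean()) ** 2)))
    if y.size < minsplit or node.ss <= _TOL:
        return node
    found = _best_split(X, y, minbucket)
    if found is None:
        return node
    _, j, thr = found
    mask = X[:, j] < thr
    node.feature, node.threshold = j, float(thr)
    node.left = _grow(X[mask], y[mask], minsplit, minbucket)
    node.right = _grow(X[~mask], y[~mask], minsplit, minbucket)
    return node


def _weakest_link_sequence(root: TreeNode):
    """Nested pruning sequence [(alpha, tree), ...], alpha ascending.

    alpha_0 = 0 holds the full tree; each subsequent entry collapses every
    internal node whose link strength g(t) = (SS(t) - SS(T_t)) / (|T_t| - 1)
    attains the current minimum.
    """
    seq = [(0.0, root.copy())]
    current = root.copy()
    while not current.is_leaf:
        links = []

        def visit(node):
            if node.is_leaf:
                return
            g = (node.ss - _risk(node)) / (_n_leaves(node) - 1)
            links.append((g, node))
            visit(node.left)
            visit(node.right)

        visit(current)
        gmin = min(g for g, _ in links)
        for g, node in links:
            if g <= gmin + _TOL * max(1.0, abs(gmin)):
                node.feature = node.threshold = None
                node.left = node.right = None
        seq.append((max(gmin, 0.0), current.copy()))
    return seq


def _prune_at(seq, alpha: float) -> TreeNode:
    """Smallest optimally pruned subtree for penalty ``alpha``."""
    chosen = seq[0][1]
    for a, tree in seq:
        if a <= alpha + _TOL * max(1.0, alpha):
            chosen = tree
        else:
            break
    return chosen.copy()


# ---------------------------------------------------------------------------
# model / results

class CARTRegression:
    """CART regression model for a feature table and numeric response.

    Parameters
    ----------
    X : DataFrame or ndarray, shape (n, p)
        Training features; a DataFrame supplies feature names.
    y : array-like, shape (n,)
        Numeric response.
    minsplit : int
        Minimum rows a node must hold to be considered for splitting
        (default 4, the study setting).
    minbucket : int
        Minimum rows per leaf (default 1).
    """

    def __init__(self, X, y, minsplit: int = 4, minbucket: int = 1):
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(map(str, X.columns))
            Xarr = X.to_numpy(dtype=float)
        else:
            Xarr = np.asarray(X, dtype=float)
            if Xarr.ndim != 2:
                raise ValueError("X must be 2-D")
            self.feature_names = [f"x{j}" for j in range(Xarr.shape[1])]
        y = np.asarray(y, dtype=float)
        if y.ndim != 1 or y.size != Xarr.shape[0]:
            raise ValueError("y must be 1-D with one value per row of X")
        if not np.isfinite(Xarr).all():
            raise ValueError("X contains missing/non-finite values; "
                             "impute before fitting")
        if not np.isfinite(y).all():
            raise ValueError("y contains non-finite values")
        if y.size < minsplit:
            warnings.warn("fewer rows than minsplit: the tree will be a "
                          "single leaf", UserWarning, stacklevel=2)
        self.X, self.y = Xarr, y
        self.minsplit, self.minbucket = int(minsplit), int(minbucket)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       minsplit: int = 4, minbucket: int = 1):
        """Build from one DataFrame naming the response column."""
        y = data[response]
        X = data.drop(columns=[response])
        return cls(X, y, minsplit=minsplit, minbucket=minbucket)

    def fit(self) -> "CARTResults":
        root = _grow(self.X, self.y, self.minsplit, self.minbucket)
        if root.is_leaf and root.ss <= _TOL:
            warnings.warn("constant response: root-only tree", UserWarning,
                          stacklevel=2)
        seq = _weakest_link_sequence(root)
        return CARTResults(self, root, seq)


class CARTResults:
    """Fitted tree plus its cost-complexity sequence.

    Attributes
    ----------
    tree_ : TreeNode
        Root of the (possibly pruned) tree.
    cp_table : DataFrame
        One row per nested subtree, columns ``cp`` (alpha / SS_root,
        descending: row 0 is the root-only tree), ``n_leaves`` and
        ``rel_error`` (subtree SSE / SS_root). ``cross_validate`` appends
        ``xerror`` and ``xstd``.
    """

    def __init__(self, model: CARTRegression, tree: TreeNode, seq,
                 selected_cp: float | None = None):
        self.model = model
        self.tree_ = tree
        self._seq = seq
        self.selected_cp = selected_cp
        ss_root = seq[0][1].ss if seq else tree.ss
        self._ss_root = max(ss_root, _TOL)
        rows = [(a / self._ss_root, _n_leaves(t), _risk(t) / self._ss_root)
                for a, t in seq]
        self.cp_table = (pd.DataFrame(rows,
                                      columns=["cp", "n_leaves", "rel_error"])
                         .sort_values("cp", ascending=False)
                         .reset_index(drop=True))

    # -- basic accessors ---------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return _n_leaves(self.tree_)

    @property
    def used_features(self) -> list:
        names, out = self.model.feature_names, []

        def visit(node):
            if node.is_leaf:
                return
            if names[node.feature] not in out:
                out.append(names[node.feature])
            visit(node.left)
            visit(node.right)

        visit(self.tree_)
        return out

    # -- prediction --------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Route rows to leaves; returns leaf-mean predictions."""
        if isinstance(X, pd.DataFrame):
            missing = [self.model.feature_names[i]
                       for i in self._used_indices()
                       if self.model.feature_names[i] not in X.columns]
            if missing:
                raise KeyError(f"test table lacks feature(s) used by the "
                               f"tree: {missing}")
            # align by name; absent unused columns are tolerated
            Xarr = np.full((len(X), len(self.model.feature_names)), np.nan)
            for j, name in enumerate(self.model.feature_names):
                if name in X.columns:
                    Xarr[:, j] = X[name].to_numpy(dtype=float)
        else:
            Xarr = np.asarray(X, dtype=float)
            if Xarr.ndim == 1:
                Xarr = Xarr[None, :]
        preds = np.empty(Xarr.shape[0])
        for i, row in enumerate(Xarr):
            node = self.tree_
            while not node.is_leaf:
                v = row[node.feature]
                if np.isnan(v):
                    raise ValueError(
                        "missing value for feature "
                        f"{self.model.feature_names[node.feature]!r}")
                node = node.left if v < node.threshold else node.right
            preds[i] = node.mean
        return preds

    def _used_indices(self) -> list:
        out = []

        def visit(node):
            if node.is_leaf:
                return
            out.append(node.feature)
            visit(node.left)
            visit(node.right)

        visit(self.tree_)
        return sorted(set(out))

    # -- cross-validation / pruning ----------------------------------------
    def cross_validate(self, k: int = 10, seed: int = 0) -> pd.DataFrame:
        """k-fold CV error for every cp in the table (seeded random folds).

        Each held-out fold is predicted by the tree grown on the remaining
        rows and pruned at the geometric mean of the adjacent cp interval,
        mirroring the reference cost-complexity CV. ``xerror`` is the
        pooled out-of-fold SSE relative to the root risk; ``xstd`` is the
        standard error of that pooled sum. If n < k the CV degrades to
        leave-one-out with a warning.
        """
        X, y = self.model.X, self.model.y
        n = y.size
        if n < k:
            warnings.warn(f"n = {n} < {k} folds: using leave-one-out",
                          UserWarning, stacklevel=2)
            k = n
        rng = np.random.default_rng(seed)
        fold_of = np.repeat(np.arange(k), np.diff(
            np.round(np.linspace(0, n, k + 1)).astype(int)))
        fold_of = fold_of[rng.permutation(n)]

        cps = self.cp_table["cp"].to_numpy()
        betas = np.empty_like(cps)
        betas[0] = np.inf
        for j in range(1, len(cps)):
            betas[j] = np.sqrt(cps[j] * cps[j - 1])

        preds = np.empty((len(cps), n))
        for f in range(k):
            hold = fold_of == f
            Xtr, ytr = X[~hold], y[~hold]
            sub = CARTRegression(Xtr, ytr, self.model.minsplit,
                                 self.model.minbucket)
            root = _grow(sub.X, sub.y, sub.minsplit, sub.minbucket)
            seq = _weakest_link_sequence(root)
            ss_root = max(seq[0][1].ss, _TOL)
            for ci, beta in enumerate(betas):
                pruned = _prune_at(seq, beta * ss_root)
                res = CARTResults(sub, pruned, [(0.0, pruned)])
                preds[ci, hold] = res.predict(X[hold])

        table = self.cp_table.copy()
        xerr, xstd = [], []
        for ci in range(len(cps)):
            e = (y - preds[ci]) ** 2
            xerr.append(e.sum() / self._ss_root)
            # SE of the summed error, population-sd convention (matches the
            # reference CART implementation's cptable)
            xstd.append(np.sqrt(np.sum((e - e.mean()) ** 2))
                        / self._ss_root)
        table["xerror"] = xerr
        table["xstd"] = xstd
        return table

    def prune(self, cp: float) -> "CARTResults":
        """Return results holding the subtree selected by complexity cp."""
        tree = _prune_at(self._seq, cp * self._ss_root)
        return CARTResults(self.model, tree, self._seq, selected_cp=cp)

    # -- reporting -----------------------------------------------------------
    def dump_tree(self, indent: str = "  ") -> str:
        """Plain-text tree: split conditions and leaf means."""
        names = self.model.feature_names
        lines = []

        def visit(node, depth, prefix):
            pad = indent * depth
            if node.is_leaf:
                lines.append(f"{pad}{prefix}leaf: mean={node.mean:.6g} "
                             f"n={node.n}")
                return
            lines.append(f"{pad}{prefix}split: {names[node.feature]} "
                         f"< {node.threshold:.6g} (n={node.n})")
            visit(node.left, depth + 1, "yes -> ")
            visit(node.right, depth + 1, "no  -> ")

        visit(self.tree_, 0, "")
        return "\n".join(lines)

    def summary(self) -> str:
        head = (f"CART regression: n={self.model.y.size}, "
                f"p={len(self.model.feature_names)}, "
                f"minsplit={self.model.minsplit}, "
                f"leaves={self.n_leaves}")
        if self.selected_cp is not None:
            head += f", selected cp={self.selected_cp:.6g}"
        return "\n".join([
            head,
            "",
            "complexity table:",
            self.cp_table.to_string(index=False),
            "",
            "tree:",
            self.dump_tree(),
        ])


# ---------------------------------------------------------------------------
# functional wrappers

def fit_cart(X, y, minsplit: int = 4, minbucket: int = 1) -> CARTResults:
    """Fit a CART regression tree (full growth + pruning sequence)."""
    return CARTRegression(X, y, minsplit=minsplit, minbucket=minbucket).fit()


def one_se_select(cv_table: pd.DataFrame) -> float:
    """1-SE rule on a CV table with columns cp, xerror, xstd.

    Picks the largest cp (smallest tree) whose xerror does not exceed the
    minimum xerror plus one standard error of that minimum; exact ties on
    xerror therefore favor parsimony.
    """
    t = cv_table.sort_values("cp", ascending=False).reset_index(drop=True)
    imin = int(t["xerror"].idxmin())
    thr = t.loc[imin, "xerror"] + t.loc[imin, "xstd"]
    ok = t.index[t["xerror"] <= thr + _TOL]
    return float(t.loc[ok[0], "cp"])


def cv_select_cp(results: CARTResults, k: int = 10, seed: int = 0) -> float:
    """Cross-validate and apply the 1-SE rule; returns the chosen cp."""
    return one_se_select(results.cross_validate(k=k, seed=seed))


def predict(results: CARTResults, X) -> np.ndarray:
    return results.predict(X)


# ---------------------------------------------------------------------------
# correlation reporting

@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its t-statistic, degrees of freedom and p-value."""

    r: float
    t: float
    df: int
    p: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


def pearson_with_t(pred, actual) -> CorrelationResult:
    """Pearson correlation with t = r sqrt(n-2)/sqrt(1-r^2), two-sided p.

    A constant vector (e.g. a root-only tree's prediction) leaves r
    undefined: NaNs are returned with a warning, to be reported as
    non-significant, never as zero correlation. |r| = 1 yields an infinite
    t with p = 0.
    """
    x = np.asarray(pred, dtype=float)
    y = np.asarray(actual, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pred and actual must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for a correlation t-test")
    df = n - 2
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("correlation undefined for a constant vector",
                      UndefinedCorrelationWarning, stacklevel=2)
        return CorrelationResult(float("nan"), float("nan"), df, float("nan"))
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-15:
        t = float(np.sign(r) * np.inf)
        return CorrelationResult(float(np.sign(r)), t, df, 0.0)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(r, float(t), df, float(p))


class CorrelationReport:
    """Per-subscore out-of-sample correlation table (one method).

    ``frame`` has one row per subscore with columns method, r, t, df, p,
    selected_cp, n_leaves and used_features; ``models`` maps subscore to
    the pruned :class:`CARTResults` so trees can be dumped.
    """

    def __init__(self, frame: pd.DataFrame, models: dict, method: str):
        self.frame = frame
        self.models = models
        self.method = method

    def summary(self) -> str:
        cols = ["r", "t", "df", "p", "selected_cp", "n_leaves"]
        out = [f"out-of-sample correlation report — method: {self.method}",
               self.frame[cols].round(4).to_string()]
        return "\n".join(out)

    def to_csv(self, path) -> None:
        self.frame.rename_axis("subscore").to_csv(path)


def run_method_comparison(train: pd.DataFrame, test: pd.DataFrame,
                          scores: ScoreTable,
                          subscores: Sequence[str] | None = None,
                          seed: int = 0, minsplit: int = 4,
                          k: int = 10, method: str = "") -> CorrelationReport:
    """Fit, prune, predict and correlate for each subscore.

    ``train`` and ``test`` are subjects x features tables from the two
    epochs (identical columns and subject order required). Missing feature
    values are imputed with the training-set median of the feature; a
    feature missing in every training subject is dropped from both tables.
    Per-subscore CV fold seeds are derived deterministically from ``seed``.
    """
    if list(train.columns) != list(test.columns):
        raise ValueError("train/test feature name mismatch")
    if list(train.index) != list(test.index):
        raise ValueError("train/test subject order mismatch")
    missing_subj = [s for s in train.index if str(s) not in scores.subject_ids]
    if missing_subj:
        raise ValueError(f"subjects without score rows: {missing_subj}")
    if subscores is None:
        subscores = scores.subscores

    med = train.median()
    dead = med.index[med.isna()]
    if len(dead):
        warnings.warn(f"dropping {len(dead)} all-missing feature(s)",
                      UserWarning, stacklevel=2)
        train = train.drop(columns=dead)
        test = test.drop(columns=dead)
        med = med.drop(dead)
    train = train.fillna(med)
    test = test.fillna(med)

    subjects = [str(s) for s in train.index]
    rows, models = [], {}
    seeds = np.random.SeedSequence(seed).generate_state(len(subscores))
    for i, sub in enumerate(subscores):
        y = scores.frame.loc[subjects, sub].to_numpy(dtype=float)
        res = fit_cart(train, y, minsplit=minsplit)
        cp = cv_select_cp(res, k=min(k, len(y)), seed=int(seeds[i] % 2**31))
        pruned = res.prune(cp)
        pred = pruned.predict(test)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UndefinedCorrelationWarning)
            corr = pearson_with_t(pred, y)
        if not corr.defined:
            warnings.warn(f"{sub}: constant prediction (tree pruned to "
                          "root); correlation reported as undefined",
                          UndefinedCorrelationWarning, stacklevel=2)
        rows.append({"method": method, "r": corr.r, "t": corr.t,
                     "df": corr.df, "p": corr.p, "selected_cp": cp,
                     "n_leaves": pruned.n_leaves,
                     "used_features": ";".join(pruned.used_features)})
        models[sub] = pruned
    frame = pd.DataFrame(rows, index=list(subscores))
    return CorrelationReport(frame, models, method)
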