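"""Bagged decision forest with chi-squared split selection and surrogate
splits for missing features.

Trees are grown on bootstrap resamples of the patients.  At each node a
random feature subset is drawn; the split feature is the subset member
whose association with the class label has the smallest Pearson
chi-squared p-value (numeric features are pre-binned into equal-frequency
bins), a selection rule that, unlike plain impurity search, is not biased
toward many-valued features.  The cut point of the chosen feature then
maximizes the Gini impurity decrease.  Up to five surrogate rules on
other features, ranked by their agreement with the primary split beyond
the majority-direction baseline, route rows whose split feature is
missing.  Performance is always read off the out-of-bag (OOB) patients:
each patient is scored only by the trees whose bootstrap sample omitted
them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class ForestParams:
    n_trees: int = 200
    min_leaf: int = 5
    mtry: int | None = None      # default ceil(sqrt(n_features))
    n_bins: int = 4              # equal-frequency bins for the chi2 test
    n_surrogates: int = 5
    use_surrogates: bool = True


@dataclass
class _Col:
    name: str
    kind: str                    # "num" | "cat"
    x: np.ndarray                # float (NaN missing) or int codes (-1 missing)
    categories: list = field(default_factory=list)


def _prepare_columns(features: pd.DataFrame) -> list[_Col]:
    cols = []
    for name in features.columns:
        s = features[name]
        if pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s):
            cols.append(_Col(name, "num", s.to_numpy(dtype=float)))
        else:
            cats = sorted(map(str, s.dropna().unique()))
            lookup = {c: i for i, c in enumerate(cats)}
            codes = np.array(
                [lookup[str(v)] if pd.notna(v) else -1 for v in s], dtype=int
            )
            cols.append(_Col(name, "cat", codes, cats))
    return cols


# ---------------------------------------------------------------------------
# chi-squared split-feature selection

def _pearson_chi2_pvalue(table: np.ndarray) -> float:
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    stat = float(((table - exp) ** 2 / exp).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return float(stats.chi2.sf(stat, df))


def _bin_codes(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin codes for non-missing numeric values."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(edges)
    return np.searchsorted(edges, x, side="left")


def chi2_split_pvalue(values, labels, n_bins: int = 4) -> float:
    """P-value of a Pearson chi-squared independence test between one
    feature and the class labels, excluding missing values.

    Numeric features are discretized into at most `n_bins`
    equal-frequency bins; categorical features enter as-is.  A feature
    constant on its non-missing values gives p = 1.
    """
    s = pd.Series(values)
    y = np.asarray(labels)
    if pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s):
        x = s.to_numpy(dtype=float)
        ok = ~np.isnan(x)
        if ok.sum() < 2 or len(np.unique(x[ok])) < 2:
            return 1.0
        codes = _bin_codes(x[ok], n_bins)
    else:
        ok = s.notna().to_numpy()
        if ok.sum() < 2:
            return 1.0
        codes = pd.factorize(s[ok])[0]
    yb = pd.factorize(y[ok])[0]
    table = np.zeros((codes.max() + 1, yb.max() + 1))
    np.add.at(table, (codes, yb), 1)
    return _pearson_chi2_pvalue(table)


def _node_chi2(col: _Col, rows: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    if col.kind == "num":
        x = col.x[rows]
        ok = ~np.isnan(x)
        if ok.sum() < 2 or len(np.unique(x[ok])) < 2:
            return 1.0
        codes = _bin_codes(x[ok], n_bins)
    else:
        codes = col.x[rows]
        ok = codes >= 0
        if ok.sum() < 2:
            return 1.0
        codes = codes[ok]
    yy = y[rows][ok]
    table = np.zeros((int(codes.max()) + 1, 2))
    np.add.at(table, (codes, yy), 1)
    return _pearson_chi2_pvalue(table)


# ---------------------------------------------------------------------------
# split search (Gini)

def gini_impurity(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p ** 2).sum())


def _split_gain(n1L, nL, n1_tot, n_tot) -> float:
    """Gini decrease of a binary split given class-1 prefix counts."""
    n0L = nL - n1L
    n1R = n1_tot - n1L
    nR = n_tot - nL
    n0R = nR - n1R
    parent = gini_impurity(np.array([n_tot - n1_tot, n1_tot]))
    gl = gini_impurity(np.array([n0L, n1L]))
    gr = gini_impurity(np.array([n0R, n1R]))
    return parent - (nL * gl + nR * gr) / n_tot


def _best_split_num(x, y, min_leaf):
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    n1 = int(ys.sum())
    cum1 = np.cumsum(ys)
    boundaries = np.flatnonzero(np.diff(xs) > 0)  # split after index i
    best = (None, -np.inf)
    for i in boundaries:
        nL = i + 1
        if nL < min_leaf or n - nL < min_leaf:
            continue
        gain = _split_gain(int(cum1[i]), nL, n1, n)
        if gain > best[1]:
            # threshold at the left order statistic keeps routing purely
            # rank-based (invariant under monotone feature transforms)
            best = (xs[i], gain)
    return best  # (threshold, gain)


def _best_split_cat(codes, y, min_leaf):
    cats = np.unique(codes)
    if len(cats) < 2:
        return None, -np.inf
    n = len(codes)
    n1 = int(y.sum())
    cnt = np.zeros((len(cats), 2))
    pos = {c: i for i, c in enumerate(cats)}
    np.add.at(cnt, ([pos[c] for c in codes], y), 1)
    best = (None, -np.inf)
    if len(cats) <= 8:
        # exhaustive over proper subsets, fixing the first category's side
        for mask in range(1, 2 ** (len(cats) - 1)):
            members = [cats[j] for j in range(len(cats)) if mask >> j & 1]
            sel = np.isin(codes, members)
            nL = int(sel.sum())
            if nL < min_leaf or n - nL < min_leaf:
                continue
            n1L = int(y[sel].sum())
            gain = _split_gain(n1L, nL, n1, n)
            if gain > best[1]:
                best = (frozenset(members), gain)
    else:
        rate = cnt[:, 1] / cnt.sum(axis=1)
        order = np.argsort(rate, kind="stable")
        run1 = np.cumsum(cnt[order, 1])
        runn = np.cumsum(cnt[order].sum(axis=1))
        for j in range(len(cats) - 1):
            nL = int(runn[j])
            if nL < min_leaf or n - nL < min_leaf:
                continue
            gain = _split_gain(int(run1[j]), nL, n1, n)
            if gain > best[1]:
                best = (frozenset(cats[order[: j + 1]].tolist()), gain)
    return best


# ---------------------------------------------------------------------------
# surrogate rules

@dataclass
class Surrogate:
    feature: int
    kind: str
    rule: object          # (threshold, left_if_le) or frozenset of codes -> left
    agreement: float
    gain: float           # Gini decrease of the surrogate rule at this node


def _routes_left(col: _Col, rule, idx: np.ndarray):
    """(defined_mask, left_mask) of `rule` applied to rows `idx`."""
    if col.kind == "num":
        x = col.x[idx]
        defined = ~np.isnan(x)
        thr, left_if_le = rule
        left = (x <= thr) if left_if_le else (x > thr)
    else:
        codes = col.x[idx]
        defined = codes >= 0
        left = np.isin(codes, list(rule))
    return defined, left & defined


def _surrogate_for(col: _Col, rows, prim_defined, prim_left, y):
    """Best rule on `col` mimicking the primary routing; None if it does
    not beat the majority-direction baseline."""
    if col.kind == "num":
        x = col.x[rows]
        co = prim_defined & ~np.isnan(x)
    else:
        co = prim_defined & (col.x[rows] >= 0)
    m = int(co.sum())
    if m < 2:
        return None
    dirL = prim_left[co]
    nL = int(dirL.sum())
    baseline = max(nL, m - nL) / m
    if col.kind == "num":
        xv = col.x[rows][co]
        order = np.argsort(xv, kind="stable")
        xs, ds = xv[order], dirL[order]
        boundaries = np.flatnonzero(np.diff(xs) > 0)
        if boundaries.size == 0:
            return None
        cumL = np.cumsum(ds)
        best_agree, best_rule = -1.0, None
        for i in boundaries:
            a = (int(cumL[i]) + (m - nL) - (i + 1 - int(cumL[i]))) / m
            thr = xs[i]
            for agree, orient in ((a, True), (1.0 - a, False)):
                if agree > best_agree:
                    best_agree, best_rule = agree, (thr, orient)
        rule, agreement = best_rule, best_agree
    else:
        codes = col.x[rows][co]
        cats = np.unique(codes)
        left_members, agree_n = [], 0
        for c in cats:
            sel = codes == c
            nlc = int(dirL[sel].sum())
            nc = int(sel.sum())
            if nlc * 2 > nc:   # ties go right
                left_members.append(int(c))
                agree_n += nlc
            else:
                agree_n += nc - nlc
        rule, agreement = frozenset(left_members), agree_n / m
    if agreement <= baseline + 1e-12:
        return None
    # impurity decrease of the surrogate's own routing (for importances)
    defined, left = _routes_left(col, rule, rows)
    yy = y[rows][defined]
    ll = left[defined]
    if defined.sum() == 0 or ll.sum() in (0, defined.sum()):
        gain = 0.0
    else:
        gain = _split_gain(int(yy[ll].sum()), int(ll.sum()), int(yy.sum()),
                           int(defined.sum()))
    return Surrogate(feature=-1, kind=col.kind, rule=rule,
                     agreement=agreement, gain=max(gain, 0.0))


# ---------------------------------------------------------------------------
# tree

@dataclass
class TreeNode:
    n: int
    counts: np.ndarray
    gini: float
    # internal nodes
    feature: int | None = None
    kind: str | None = None
    rule: object = None
    gain: float = 0.0
    surrogates: list = field(default_factory=list)
    majority_left: bool = True
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    # leaves
    prob: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def _leaf(y, rows) -> TreeNode:
    counts = np.bincount(y[rows], minlength=2)
    return TreeNode(n=len(rows), counts=counts, gini=gini_impurity(counts),
                    prob=counts[1] / max(counts.sum(), 1))


def grow_tree(cols: list[_Col], y: np.ndarray, rows: np.ndarray,
              params: ForestParams, rng: np.random.Generator) -> TreeNode:
    """Grow one chi-squared/Gini tree with surrogate rules on `rows`."""
    p = len(cols)
    mtry = params.mtry or int(np.ceil(np.sqrt(p)))
    mtry = min(mtry, p)

    def grow(rows: np.ndarray) -> TreeNode:
        counts = np.bincount(y[rows], minlength=2)
        if counts.min() == 0 or len(rows) < 2 * params.min_leaf:
            return _leaf(y, rows)
        subset = rng.choice(p, size=mtry, replace=False)
        pvals = np.array([_node_chi2(cols[f], rows, y, params.n_bins)
                          for f in subset])
        pmin = pvals.min()
        if pmin >= 1.0 - 1e-12 and len(np.unique(pvals)) == 1:
            pass  # still try: a constant-p subset can carry a usable cut
        tied = np.flatnonzero(pvals <= pmin + 1e-12)
        best_f, best_rule, best_gain = None, None, -np.inf
        for j in tied:  # tie-break: larger Gini decrease, then draw order
            f = int(subset[j])
            col = cols[f]
            if col.kind == "num":
                x = col.x[rows]
                ok = ~np.isnan(x)
                if ok.sum() < 2 * params.min_leaf:
                    continue
                rule, gain = _best_split_num(x[ok], y[rows][ok], params.min_leaf)
                rule = (rule, True) if rule is not None else None
            else:
                codes = col.x[rows]
                ok = codes >= 0
                if ok.sum() < 2 * params.min_leaf:
                    continue
                rule, gain = _best_split_cat(codes[ok], y[rows][ok],
                                             params.min_leaf)
            if rule is not None and gain > best_gain + 1e-15:
                best_f, best_rule, best_gain = f, rule, gain
        if best_f is None or best_gain <= 0:
            return _leaf(y, rows)
        col = cols[best_f]
        prim_defined, prim_left = _routes_left(col, best_rule, rows)

        surrogates: list[Surrogate] = []
        if params.use_surrogates and params.n_surrogates > 0:
            for f in range(p):
                if f == best_f:
                    continue
                s = _surrogate_for(cols[f], rows, prim_defined, prim_left, y)
                if s is not None:
                    s.feature = f
                    surrogates.append(s)
            surrogates.sort(key=lambda s: (-s.agreement, s.feature))
            surrogates = surrogates[: params.n_surrogates]

        majority_left = prim_left.sum() * 2 >= prim_defined.sum()
        go_left = prim_left.copy()
        unresolved = ~prim_defined
        for s in surrogates:
            if not unresolved.any():
                break
            defined, left = _routes_left(cols[s.feature], s.rule, rows)
            use = unresolved & defined
            go_left[use] = left[use]
            unresolved &= ~defined
        go_left[unresolved] = majority_left

        left_rows = rows[go_left]
        right_rows = rows[~go_left]
        if len(left_rows) == 0 or len(right_rows) == 0:
            return _leaf(y, rows)
        node = TreeNode(n=len(rows), counts=counts, gini=gini_impurity(counts),
                        feature=best_f, kind=col.kind, rule=best_rule,
                        gain=best_gain, surrogates=surrogates,
                        majority_left=majority_left)
        node.left = grow(left_rows)
        node.right = grow(right_rows)
        return node

    return grow(np.asarray(rows))


def _predict_row(node: TreeNode, cols: list[_Col], i: int) -> float:
    while not node.is_leaf:
        col = cols[node.feature]
        defined, left = _routes_left(col, node.rule, np.array([i]))
        if defined[0]:
            node = node.left if left[0] else node.right
            continue
        routed = False
        for s in node.surrogates:
            d, l = _routes_left(cols[s.feature], s.rule, np.array([i]))
            if d[0]:
                node = node.left if l[0] else node.right
                routed = True
                break
        if not routed:
            node = node.left if node.majority_left else node.right
    return node.prob


# ---------------------------------------------------------------------------
# forest

@dataclass
class ForestModel:
    trees: list
    inbag: np.ndarray              # (n_trees, n) bootstrap multiplicities
    params: ForestParams
    feature_names: list[str]
    classes_: np.ndarray
    columns: list = field(default_factory=list)   # training _Col cache
    seed: int | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def oob_mask(self) -> np.ndarray:
        return self.inbag == 0

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        cols = _prepare_columns(features[self.feature_names])
        n = len(features)
        out = np.zeros(n)
        for tree in self.trees:
            out += [_predict_row(tree, cols, i) for i in range(n)]
        return out / self.n_trees


def _ordered_classes(y_raw: np.ndarray) -> np.ndarray:
    """Class order (negative, positive); 'high' variability is positive."""
    classes = np.unique(y_raw)
    if set(classes.tolist()) == {"low", "high"}:
        return np.array(["low", "high"])
    return classes


def fit_forest(features: pd.DataFrame, labels, params: ForestParams | None = None,
               seed: int | None = None) -> ForestModel:
    """Fit a bagged surrogate-split forest.

    `labels` holds exactly two classes; scores are probabilities of the
    positive class ('high' for low/high labels, else the
    lexicographically larger one).
    """
    params = params or ForestParams()
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes!r}")
    classes = _ordered_classes(y_raw)
    y = (y_raw == classes[1]).astype(int)
    n = len(y)
    if n < 20:
        raise ValueError("need at least 20 patients")
    cols = _prepare_columns(features)
    ss = np.random.SeedSequence(seed)
    trees, inbag = [], np.zeros((params.n_trees, n), dtype=int)
    for t, child in enumerate(ss.spawn(params.n_trees)):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        inbag[t] = np.bincount(idx, minlength=n)
        trees.append(grow_tree(cols, y, idx, params, rng))
    return ForestModel(trees=trees, inbag=inbag, params=params,
                       feature_names=list(features.columns),
                       classes_=classes, columns=cols, seed=seed)


def oob_predict(forest: ForestModel) -> np.ndarray:
    """Per-patient OOB score: vote average over trees that omitted them.

    Patients in-bag in every tree get NaN (with a warning).
    """
    oob = forest.oob_mask()
    n = oob.shape[1]
    total = np.zeros(n)
    count = oob.sum(axis=0)
    for t, tree in enumerate(forest.trees):
        rows = np.flatnonzero(oob[t])
        for i in rows:
            total[i] += _predict_row(tree, forest.columns, i)
    with np.errstate(invalid="ignore"):
        scores = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    if (count == 0).any():
        warnings.warn(f"{int((count == 0).sum())} patients were never out of "
                      "bag; their scores are missing")
    return scores


def oob_fraction(forest: ForestModel) -> float:
    """Mean per-tree fraction of omitted patients (expected ~ 1/e)."""
    return float(forest.oob_mask().mean())


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci: tuple[float, float]
    level: float
    n_boot: int
    scores: np.ndarray
    labels: np.ndarray


def roc_auc_ci(scores, labels, n_boot: int = 2000, level: float = 0.95,
               seed: int | None = None) -> RocResult:
    """ROC curve with rank-statistic AUC and percentile bootstrap CI.

    NaN scores (never-OOB patients) are dropped with a warning; the CI
    resamples patients `n_boot` times at confidence `level`.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    ok = ~np.isnan(scores)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} unscored patients from AUC")
        scores, y = scores[ok], y[ok]
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("both classes must be present among scored patients")
    classes = _ordered_classes(y)
    yb = (y == classes[1]).astype(int)
    auc = float(roc_auc_score(yb, scores))
    fpr, tpr, _ = roc_curve(yb, scores)
    rng = np.random.default_rng(seed)
    boots = []
    n = len(yb)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if len(np.unique(yb[idx])) < 2:
            continue
        boots.append(roc_auc_score(yb[idx], scores[idx]))
    alpha = 1.0 - level
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return RocResult(fpr=fpr, tpr=tpr, auc=auc, ci=(float(lo), float(hi)),
                     level=level, n_boot=n_boot, scores=scores, labels=yb)


def _oob_auc(features, labels, params, seed) -> float:
    forest = fit_forest(features, labels, params, seed=seed)
    scores = oob_predict(forest)
    y = np.asarray(labels)
    ok = ~np.isnan(scores)
    yb = (y == forest.classes_[1]).astype(int)
    if len(np.unique(yb[ok])) < 2:
        return 0.5
    return float(roc_auc_score(yb[ok], scores[ok]))


def forward_select(features: pd.DataFrame, labels, params: ForestParams | None = None,
                   max_features: int = 15, min_gain: float = 0.001,
                   seed: int | None = None):
    """Greedy forward selection maximizing OOB AUC.

    Starting from the empty set (baseline AUC 0.5), each round refits a
    forest on the current set plus each remaining candidate and adds the
    candidate with the best OOB AUC; stops when the best improvement is
    below `min_gain` or `max_features` is reached.  Deterministic given
    `seed`.

    Returns (selected_names, trace) where trace has one row per
    evaluated candidate.
    """
    params = params or ForestParams()
    candidates = list(features.columns)
    selected: list[str] = []
    current = 0.5
    rows = []
    round_i = 0
    while candidates and len(selected) < max_features:
        round_i += 1
        best_name, best_auc = None, -np.inf
        for j, name in enumerate(candidates):
            sub_seed = int(np.random.SeedSequence(
                [0 if seed is None else seed, round_i, j]).generate_state(1)[0]
                % (2**31))
            auc = _oob_auc(features[selected + [name]], labels, params, sub_seed)
            rows.append(dict(round=round_i, candidate=name, auc=auc))
            if auc > best_auc:
                best_name, best_auc = name, auc
        if best_auc - current < min_gain:
            break
        selected.append(best_name)
        candidates.remove(best_name)
        current = best_auc
    trace = pd.DataFrame(rows, columns=["round", "candidate", "auc"])
    return selected, trace


def hyperparam_search(features: pd.DataFrame, labels, space: dict,
                      budget: int = 30, seed: int | None = None):
    """Random search over forest hyperparameters, scored by OOB AUC.

    `space` maps ForestParams field names to candidate value lists.  The
    paper-level objective (maximize OOB AUC) is the contract; the search
    strategy is pluggable and random search is the default.  Budget 0
    returns the defaults.
    """
    if not space:
        raise ValueError("search space must be nonempty")
    if budget <= 0:
        return ForestParams(), pd.DataFrame()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    eval_seed = int(ss.generate_state(1)[0] % (2**31))
    keys = sorted(space)
    seen = set()
    rows = []
    best = (None, -np.inf)
    n_points = int(np.prod([len(space[k]) for k in keys]))
    for _ in range(min(budget, n_points) * 4):
        if len(seen) >= min(budget, n_points):
            break
        combo = tuple(space[k][rng.integers(len(space[k]))] for k in keys)
        if combo in seen:
            continue
        seen.add(combo)
        params = ForestParams(**dict(zip(keys, combo)))
        auc = _oob_auc(features, labels, params, eval_seed)
        rows.append(dict(**dict(zip(keys, combo)), auc=auc))
        if auc > best[1]:
            best = (params, auc)
    return best[0], pd.DataFrame(rows)


def feature_importance(forest: ForestModel) -> pd.Series:
    """Impurity importance with surrogate credit.

    Per tree, each feature accumulates the Gini decreases of the nodes it
    splits plus the decreases its surrogate rules achieve at other nodes;
    the sum is normalized by the tree's branch-node count and averaged
    over trees.
    """
    p = len(forest.feature_names)
    total = np.zeros(p)
    for tree in forest.trees:
        imp = np.zeros(p)
        branches = 0

        def walk(node):
            nonlocal branches
            if node.is_leaf:
                return
            branches += 1
            imp[node.feature] += node.gain
            for s in node.surrogates:
                imp[s.feature] += s.gain
            walk(node.left)
            walk(node.right)

        walk(tree)
        if branches > 0:
            total += imp / branches
    return pd.Series(total / forest.n_trees, index=forest.feature_names)
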