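"""Additive per-feature attribution of regression predictions.

For gradient-boosted trees the attribution is exact (TreeSHAP via
xgboost's ``pred_contribs``): per row, feature contributions plus the
base value reconstruct the margin prediction to numerical tolerance.
For models without an exact algorithm (SVR, MLP pipelines) a seeded
Shapley-sampling approximation is used and flagged as such: feature
contributions are averaged marginal effects over random feature
orderings against a background sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ml import _feature_columns

__all__ = ["AttributionResult", "feature_attribution"]


@dataclass
class AttributionResult:
    feature_names: list[str]
    values: np.ndarray          # (n_rows, n_features)
    base: np.ndarray            # (n_rows,)
    predictions: np.ndarray     # (n_rows,)
    exact: bool

    @property
    def ranking(self) -> pd.DataFrame:
        """Features ranked by mean absolute attribution (descending)."""
        mean_abs = np.abs(self.values).mean(axis=0)
        frame = pd.DataFrame(
            {"feature": self.feature_names, "mean_abs_attribution": mean_abs}
        )
        return frame.sort_values(
            ["mean_abs_attribution", "feature"], ascending=[False, True]
        ).reset_index(drop=True)

    def reconstruction_error(self) -> float:
        """max |base + sum(attributions) - prediction| over rows."""
        return float(
            np.max(np.abs(self.base + self.values.sum(axis=1) - self.predictions))
        )


def feature_attribution(
    model,
    rows: pd.DataFrame,
    seed: int = 0,
    n_permutations: int = 24,
    background_size: int = 64,
    precise: bool | None = None,
) -> AttributionResult:
    """Attribute each prediction additively to the feature columns.

    ``model`` is a fitted estimator from
    :func:`tacppk.ml.make_estimator`; ``rows`` a feature table (the
    ``target`` column, if present, is ignored).  For tree models the
    attribution algorithm is exact (path-dependent TreeSHAP); by
    default it runs in float64 on up to 500 rows and falls back to the
    booster's fast float32 implementation beyond that (``precise``
    forces either path).
    """
    features = _feature_columns(rows)
    X = rows[features].to_numpy(dtype=float)
    if _is_xgboost(model):
        if precise is None:
            precise = len(X) <= 500
        if precise:
            return _tree_attribution_float64(model, X, features)
        return _tree_attribution(model, X, features)
    return _sampling_attribution(
        model, X, features, seed=seed, n_permutations=n_permutations,
        background_size=background_size,
    )


def _is_xgboost(model) -> bool:
    try:
        from xgboost import XGBRegressor

        return isinstance(model, XGBRegressor)
    except ImportError:  # pragma: no cover
        return False


def _tree_attribution(model, X: np.ndarray, features: list[str]) -> AttributionResult:
    import xgboost as xgb

    booster = model.get_booster()
    dmat = xgb.DMatrix(X, feature_names=features)
    contribs = booster.predict(dmat, pred_contribs=True)
    values = contribs[:, :-1]
    base = contribs[:, -1]
    predictions = model.predict(X)
    return AttributionResult(
        feature_names=features,
        values=values,
        base=base,
        predictions=np.asarray(predictions, dtype=float),
        exact=True,
    )


# ---------------------------------------------------------------------------
# Float64 path-dependent TreeSHAP
# ---------------------------------------------------------------------------
#
# The booster's trees are parsed from the JSON dump (with cover
# statistics) and the standard polynomial-time path algorithm is run in
# double precision, so that per row the contributions plus the expected
# value reconstruct the margin exactly (to float64 round-off).  Node
# "cover" weights define the conditional expectations, matching the
# booster's own tree_path_dependent behaviour.


class _PathElement:
    __slots__ = ("d", "z", "o", "w")

    def __init__(self, d, z, o, w):
        self.d, self.z, self.o, self.w = d, z, o, w


def _extend(path, pz, po, pi):
    l = len(path)
    out = [_PathElement(e.d, e.z, e.o, e.w) for e in path]
    out.append(_PathElement(pi, pz, po, 1.0 if l == 0 else 0.0))
    for i in range(l - 1, -1, -1):
        out[i + 1].w += po * out[i].w * (i + 1) / (l + 1)
        out[i].w = pz * out[i].w * (l - i) / (l + 1)
    return out


def _unwind(path, i):
    l = len(path) - 1
    out = [_PathElement(e.d, e.z, e.o, e.w) for e in path]
    n = out[l].w
    if out[i].o != 0:
        for j in range(l - 1, -1, -1):
            t = out[j].w
            out[j].w = n * (l + 1) / ((j + 1) * out[i].o)
            n = t - out[j].w * out[i].z * (l - j) / (l + 1)
    else:
        for j in range(l - 1, -1, -1):
            out[j].w = out[j].w * (l + 1) / (out[i].z * (l - j))
    for j in range(i, l):
        out[j].d, out[j].z, out[j].o = out[j + 1].d, out[j + 1].z, out[j + 1].o
    return out[:-1]


def _unwound_sum(path, i):
    return sum(e.w for e in _unwind(path, i))


def _shap_recurse(tree, node_id, path, pz, po, pi, x, phi):
    node = tree[node_id]
    path = _extend(path, pz, po, pi)
    if node["leaf"] is not None:
        for i in range(1, len(path)):
            e = path[i]
            phi[e.d] += _unwound_sum(path, i) * (e.o - e.z) * node["leaf"]
        return
    feat = node["feature"]
    # the booster compares in float32; mirror it to route identically
    hot = node["yes"] if np.float32(x[feat]) < np.float32(node["threshold"]) else node["no"]
    cold = node["no"] if hot == node["yes"] else node["yes"]
    iz, io = 1.0, 1.0
    k = next((i for i in range(1, len(path)) if path[i].d == feat), None)
    if k is not None:
        iz, io = path[k].z, path[k].o
        path = _unwind(path, k)
    cover = node["cover"]
    _shap_recurse(tree, hot, path, iz * tree[hot]["cover"] / cover, io, feat, x, phi)
    _shap_recurse(tree, cold, path, iz * tree[cold]["cover"] / cover, 0.0, feat, x, phi)


def _parse_booster(model) -> tuple[list[dict], float]:
    import json

    booster = model.get_booster()
    dumps = booster.get_dump(with_stats=True, dump_format="json")
    config = json.loads(booster.save_config())
    base_score = float(
        config["learner"]["learner_model_param"]["base_score"]
    )
    trees = []
    for dump in dumps:
        nodes: dict[int, dict] = {}

        def walk(obj):
            nid = obj["nodeid"]
            if "leaf" in obj:
                nodes[nid] = {
                    "leaf": float(obj["leaf"]),
                    "cover": float(obj["cover"]),
                }
            else:
                nodes[nid] = {
                    "leaf": None,
                    "feature": int(str(obj["split"]).lstrip("f"))
                    if str(obj["split"]).startswith("f")
                    else obj["split"],
                    "threshold": float(obj["split_condition"]),
                    "yes": obj["yes"],
                    "no": obj["no"],
                    "cover": float(obj["cover"]),
                }
                for child in obj["children"]:
                    walk(child)
            return nid

        walk(json.loads(dump))
        trees.append(nodes)
    return trees, base_score


def _tree_expected(tree, node_id=0) -> float:
    node = tree[node_id]
    if node["leaf"] is not None:
        return node["leaf"]
    cover = node["cover"]
    return (
        tree[node["yes"]]["cover"] / cover * _tree_expected(tree, node["yes"])
        + tree[node["no"]]["cover"] / cover * _tree_expected(tree, node["no"])
    )


def _tree_predict(tree, x) -> float:
    node = tree[0]
    while node["leaf"] is None:
        go_yes = np.float32(x[node["feature"]]) < np.float32(node["threshold"])
        node = tree[node["yes"] if go_yes else node["no"]]
    return node["leaf"]


def _tree_attribution_float64(
    model, X: np.ndarray, features: list[str]
) -> AttributionResult:
    trees, base_score = _parse_booster(model)
    n, k = X.shape
    name_to_idx = {name: i for i, name in enumerate(features)}
    values = np.zeros((n, k))
    expected = sum(_tree_expected(t) for t in trees) + base_score
    predictions = np.empty(n)
    for r in range(n):
        x = X[r]
        phi: dict = {}
        margin = base_score
        for tree in trees:
            margin += _tree_predict(tree, x)
            _shap_recurse(tree, 0, [], 1.0, 1.0, -1, x, _DefaultPhi(phi))
        predictions[r] = margin
        for feat, val in phi.items():
            idx = feat if isinstance(feat, int) else name_to_idx[feat]
            values[r, idx] = val
    base = np.full(n, expected)
    return AttributionResult(
        feature_names=features,
        values=values,
        base=base,
        predictions=predictions,
        exact=True,
    )


class _DefaultPhi(dict):
    """phi accumulator accepting += on absent keys."""

    def __init__(self, store):
        self._store = store

    def __getitem__(self, key):
        return self._store.get(key, 0.0)

    def __setitem__(self, key, value):
        self._store[key] = value


def _sampling_attribution(
    model,
    X: np.ndarray,
    features: list[str],
    seed: int,
    n_permutations: int,
    background_size: int,
) -> AttributionResult:
    rng = np.random.default_rng(seed)
    n, k = X.shape
    bg_idx = rng.choice(n, size=min(background_size, n), replace=False)
    background = X[bg_idx]
    values = np.zeros((n, k))
    base = np.zeros(n)
    for _ in range(n_permutations):
        order = rng.permutation(k)
        z = background[rng.integers(len(background), size=n)].copy()
        prev = model.predict(z)
        base += prev
        for j in order:
            z[:, j] = X[:, j]
            cur = model.predict(z)
            values[:, j] += cur - prev
            prev = cur
    values /= n_permutations
    base /= n_permutations
    predictions = model.predict(X)
    return AttributionResult(
        feature_names=features,
        values=values,
        base=base,
        predictions=np.asarray(predictions, dtype=float),
        exact=False,
    )
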