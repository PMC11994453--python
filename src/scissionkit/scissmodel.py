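"""Gradient-boosted regression of the blunt rate on protospacer/guide pairs.

Feature encoding ("full" flavor): for each of the 20 protospacer positions a
4x4 indicator matrix crosses the protospacer base (rows) with the guide base
(columns); the single set cell marks the observed pair. Matrices are
flattened column-major (guide base outer, protospacer base inner, A<C<G<T)
and concatenated into a 320-long one-hot vector, followed by the mismatch
counts in the non-seed (positions 1-10) and seed (11-20) halves — 322
variables in total. The "reduced" flavor keeps positions 11-20 only
(160 one-hot + seed mismatch count = 161 variables); it is the flavor used
for variant-allele predictions where only the PAM-proximal context matters.

The response is the pseudocounted log2 blunt rate of the site (see
:mod:`scissionkit.scission`). The regressor is a 1000-tree gradient-boosted
ensemble of unlimited-depth trees with dropout-style (DART) boosting and
5-fold cross-validation. With the default dropout rate of 0 the DART
ensemble is mathematically identical to plain gradient boosting, and the
fit is routed through the cached prediction code path; setting
``rate_drop > 0`` switches to the explicit DART booster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats
from sklearn.model_selection import KFold

from ._seq import BASES, check_spacer

N_POSITIONS = 20
CELLS_PER_POS = 16
FULL_ONEHOT = 320
REDUCED_ONEHOT = 160


def _feature_names(flavor: str) -> list[str]:
    positions = range(1, 21) if flavor == "full" else range(11, 21)
    names = [
        f"pos{p}_t{t}_g{g}"
        for p in positions
        for g in BASES  # guide base outer (column-major over the 4x4 matrix)
        for t in BASES  # protospacer base inner
    ]
    if flavor == "full":
        names += ["mm_nonseed", "mm_seed"]
    else:
        names += ["mm_seed"]
    return names


def encode_pair(protospacer_seq: str, guide_spacer: str, flavor: str = "full") -> np.ndarray:
    """Encode one protospacer/guide pair into the model's feature vector."""
    if flavor not in ("full", "reduced"):
        raise ValueError("flavor must be 'full' or 'reduced'")
    proto = check_spacer(protospacer_seq)
    guide = check_spacer(guide_spacer)
    positions = range(20) if flavor == "full" else range(10, 20)
    onehot = np.zeros(len(list(positions)) * CELLS_PER_POS, dtype=np.float32)
    positions = range(20) if flavor == "full" else range(10, 20)
    for k, i in enumerate(positions):
        g = BASES.index(guide[i])
        t = BASES.index(proto[i])
        onehot[k * CELLS_PER_POS + g * 4 + t] = 1.0
    mm_nonseed = sum(1 for i in range(10) if proto[i] != guide[i])
    mm_seed = sum(1 for i in range(10, 20) if proto[i] != guide[i])
    if flavor == "full":
        extra = [mm_nonseed, mm_seed]
    else:
        extra = [mm_seed]
    return np.concatenate([onehot, np.array(extra, dtype=np.float32)])


def encode_batch(protospacers, guides, flavor: str = "full") -> np.ndarray:
    return np.vstack([encode_pair(p, g, flavor) for p, g in zip(protospacers, guides)])


@dataclass
class BluntRateModel:
    """A fitted blunt-rate regressor plus its training metadata."""

    regressor: xgb.XGBRegressor
    flavor: str
    feature_names: list[str]
    seed: int
    n_instances: int
    cv_pearson_r: float
    params: dict = field(default_factory=dict)

    def predict(self, protospacers, guides) -> np.ndarray:
        X = encode_batch(protospacers, guides, self.flavor)
        return self.regressor.predict(X)


def _make_regressor(seed: int, n_trees: int, rate_drop: float, learning_rate: float):
    common = dict(
        n_estimators=n_trees,
        max_depth=0,  # unlimited depth
        grow_policy="lossguide",
        tree_method="hist",
        learning_rate=learning_rate,
        n_jobs=1,
        random_state=seed,
    )
    if rate_drop > 0:
        reg = xgb.XGBRegressor(booster="dart", rate_drop=rate_drop, **common)
    else:
        # zero-dropout DART == plain gradient boosting; use the cached fast path
        reg = xgb.XGBRegressor(booster="gbtree", **common)
    # xgboost's save_model still expects the pre-1.6 scikit-learn marker
    reg._estimator_type = "regressor"
    return reg


def select_training_instances(
    scission_table: pd.DataFrame,
    min_proximal: int = 16,
    per_guide_cap: int = 100,
    seed: int = 0,
    staggered_cut: float = 0.2,
    blunt_cut: float = 0.8,
) -> pd.DataFrame:
    """Pick training instances from a scission table.

    Sites need at least ``min_proximal`` raw PAM-proximal molecules. Per
    guide, the blunt/staggered class imbalance K = N(blunt_fraction <
    ``staggered_cut``) / N(blunt_fraction > ``blunt_cut``) is corrected by
    subsampling the majority class toward parity (retain staggered with
    probability 1/K when K >= 1, retain blunt with probability K when
    K < 1), and at most ``per_guide_cap`` sites are kept, highly promiscuous
    guides being downsampled at random. Deterministic under ``seed``.
    """
    if scission_table.empty:
        raise ValueError("empty scission table")
    rng = np.random.default_rng(seed)
    table = scission_table[scission_table["proximal_total"] >= min_proximal]
    kept = []
    for _, group in table.groupby("guide", sort=True):
        bf = group["blunt_fraction"]
        n_stag = int((bf < staggered_cut).sum())
        n_blunt = int((bf > blunt_cut).sum())
        sel = np.ones(len(group), dtype=bool)
        if n_stag and n_blunt and n_stag != n_blunt:
            K = n_stag / n_blunt
            u = rng.random(len(group))
            if K >= 1:
                stag_mask = (bf < staggered_cut).to_numpy()
                sel &= ~stag_mask | (u < 1 / K)
            else:
                blunt_mask = (bf > blunt_cut).to_numpy()
                sel &= ~blunt_mask | (u < K)
        sub = group[sel]
        if len(sub) > per_guide_cap:
            idx = rng.choice(len(sub), size=per_guide_cap, replace=False)
            sub = sub.iloc[np.sort(idx)]
        kept.append(sub)
    return pd.concat(kept).reset_index(drop=True)


def train_blunt_model(
    instances: pd.DataFrame,
    flavor: str = "full",
    seed: int = 0,
    n_trees: int = 1000,
    n_folds: int = 5,
    rate_drop: float = 0.0,
    learning_rate: float = 0.3,
    response_col: str = "log2_blunt_rate",
) -> tuple[BluntRateModel, dict]:
    """Fit the cross-validated blunt-rate regressor.

    Returns the model (refit on all instances) and a CV report holding the
    Pearson correlation between out-of-fold predictions and the observed
    response. Needs >= 100 instances and a non-constant response.
    """
    if len(instances) < 100:
        raise ValueError("need at least 100 training instances")
    y = instances[response_col].to_numpy(dtype=np.float32)
    if np.std(y) == 0:
        raise ValueError("degenerate (constant) response")
    X = encode_batch(instances["protospacer"], instances["guide_spacer"], flavor)

    oof = np.full(len(y), np.nan, dtype=np.float32)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in kf.split(X):
        reg = _make_regressor(seed, n_trees, rate_drop, learning_rate)
        reg.fit(X[train_idx], y[train_idx])
        oof[test_idx] = reg.predict(X[test_idx])
    cv_r = float(stats.pearsonr(oof, y).statistic)

    final = _make_regressor(seed, n_trees, rate_drop, learning_rate)
    final.fit(X, y)
    model = BluntRateModel(
        regressor=final,
        flavor=flavor,
        feature_names=_feature_names(flavor),
        seed=seed,
        n_instances=len(y),
        cv_pearson_r=cv_r,
        params={
            "n_trees": n_trees, "n_folds": n_folds, "rate_drop": rate_drop,
            "learning_rate": learning_rate,
        },
    )
    report = {"cv_pearson_r": cv_r, "n_instances": len(y), "oof_predictions": oof}
    return model, report


def predict_blunt_rate(model: BluntRateModel, pairs) -> np.ndarray:
    """Predicted log2 blunt rate per (protospacer, guide) pair, order kept."""
    if isinstance(pairs, pd.DataFrame):
        protos, guides = pairs["protospacer"], pairs["guide_spacer"]
    else:
        protos, guides = zip(*pairs)
    return model.predict(list(protos), list(guides))


def save_model(model: BluntRateModel, path_prefix: str) -> None:
    """Serialize to ``<prefix>.xgb.json`` + ``<prefix>.meta.json``."""
    model.regressor.save_model(f"{path_prefix}.xgb.json")
    meta = {
        "flavor": model.flavor,
        "seed": model.seed,
        "n_instances": model.n_instances,
        "cv_pearson_r": model.cv_pearson_r,
        "params": model.params,
    }
    with open(f"{path_prefix}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_model(path_prefix: str) -> BluntRateModel:
    with open(f"{path_prefix}.meta.json") as fh:
        meta = json.load(fh)
    reg = xgb.XGBRegressor()
    reg._estimator_type = "regressor"
    reg.load_model(f"{path_prefix}.xgb.json")
    return BluntRateModel(
        regressor=reg,
        flavor=meta["flavor"],
        feature_names=_feature_names(meta["flavor"]),
        seed=meta["seed"],
        n_instances=meta["n_instances"],
        cv_pearson_r=meta["cv_pearson_r"],
        params=meta.get("params", {}),
    )


def feature_importance(model: BluntRateModel) -> pd.DataFrame:
    """Per-variable gain importance, scaled so the top variable is 1."""
    booster = model.regressor.get_booster()
    scores = booster.get_score(importance_type="gain")
    raw = np.array(
        [scores.get(f"f{i}", 0.0) for i in range(len(model.feature_names))]
    )
    top = raw.max() if raw.max() > 0 else 1.0
    out = pd.DataFrame(
        {"variable": model.feature_names, "gain": raw, "importance": raw / top}
    )
    return out.sort_values("importance", ascending=False).reset_index(drop=True)


def position_base_importance(model: BluntRateModel) -> pd.DataFrame:
    """Importance aggregated per (protospacer position, protospacer base).

    Sums the gain of the four guide-base cells of each (position, base) and
    rescales to the most important position+nucleotide.
    """
    table = feature_importance(model)
    cells = table[table["variable"].str.startswith("pos")].copy()
    cells["position"] = cells["variable"].str.extract(r"pos(\d+)_").astype(int)
    cells["proto_base"] = cells["variable"].str.extract(r"_t([ACGT])_")
    agg = cells.groupby(["position", "proto_base"])["gain"].sum().reset_index()
    top = agg["gain"].max() or 1.0
    agg["importance"] = agg["gain"] / top
    return agg.sort_values("importance", ascending=False).reset_index(drop=True)


def per_position_effect(scission_table: pd.DataFrame, response_col: str = "log2_blunt_rate") -> pd.DataFrame:
    """Per-position nucleotide effects on the observed blunt rate.

    For each protospacer position independently, a least-squares fit of the
    response on the one-hot base indicators under a sum-to-zero contrast —
    equivalently, each base's coefficient is its group mean minus the mean
    of the observed group means. Positions where a base never occurs get a
    NaN coefficient and ``defined=False`` for that base.
    """
    if len(scission_table) < 50:
        raise ValueError("need at least 50 sites")
    y = scission_table[response_col].to_numpy(dtype=float)
    protos = scission_table["protospacer"].astype(str)
    rows = []
    for pos in range(1, 21):
        base_at = protos.str[pos - 1]
        means = {b: y[(base_at == b).to_numpy()].mean() if (base_at == b).any() else np.nan
                 for b in BASES}
        observed = [m for m in means.values() if not np.isnan(m)]
        center = np.mean(observed)
        for b in BASES:
            rows.append(
                {
                    "position": pos,
                    "base": b,
                    "coefficient": means[b] - center if not np.isnan(means[b]) else np.nan,
                    "defined": not np.isnan(means[b]),
                }
            )
    return pd.DataFrame(rows)


def combo_grid_17_18(model: BluntRateModel, background_sequences) -> pd.DataFrame:
    """Mean predicted blunt rate for all 16 base combinations at 17 and 18.

    Each combination is substituted into every background 20-mer (guide =
    protospacer, no mismatches) and the predictions are averaged; rows are
    the position-17 base, columns the position-18 base.
    """
    backgrounds = [check_spacer(s) for s in background_sequences]
    if len(backgrounds) < 100:
        raise ValueError("need at least 100 background sequences")
    grid = pd.DataFrame(index=list(BASES), columns=list(BASES), dtype=float)
    for b17 in BASES:
        for b18 in BASES:
            seqs = [s[:16] + b17 + b18 + s[18:] for s in backgrounds]
            preds = model.predict(seqs, seqs)
            grid.loc[b17, b18] = float(np.mean(preds))
    grid.index.name = "base17"
    grid.columns.name = "base18"
    return grid
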