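"""Cross-validation scenarios and prediction-accuracy evaluation.

Two scenarios are implemented over adjusted phenotypes:

* Scenario I: random line-level 80/20 training/validation splits, repeated
  over cycles; the same split is shared across traits and approaches within
  a cycle so uni-/multi-trait comparisons use identical folds.  Validation
  lines are held out in the environment under evaluation; for the
  multi-environment approaches their records in the other environments
  remain in training (CV2-style) unless full-line holdout is requested.

* Scenario II: forward prediction of a designated target environment from
  named training-environment sets (DT1: one earlier season; DT2: the other
  locations; DT3: their union).

Accuracy is the Pearson correlation between observed and predicted adjusted
phenotypes in the validation set, tabulated per model x approach x
environment x trait x cycle.  Model comparison within a cell uses the
Tukey-Kramer honestly-significant-difference test over cycles, summarized
as compact letter groupings.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .bayes import (
    MCMCSettings,
    bgge_predictions,
    bmtme_predictions,
    build_ge_kernels,
    fit_bgge,
    fit_bmtme,
    fit_mcmc_mixed,
    gblup_extend,
)
from .deep import MLPConfig, build_design_matrices, build_dl_inputs, predict_mlp, train_mlp
from .panel import KinshipMatrix, validate_phenotypes

APPROACHES = ("UTUE", "UTME", "MTUE", "MTME")
MODEL_APPROACHES = {
    "mcmc_mixed": {"UTUE", "MTUE"},
    "bgge": {"UTME"},
    "bmtme": {"MTME"},
    "dl": {"UTUE", "UTME", "MTUE", "MTME"},
}


@dataclass
class CVScheme:
    scenario: str = "random_holdout"
    train_fraction: float = 0.8
    n_cycles: int = 50
    seed: int = 0
    full_line_holdout: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass
class CVSplit:
    train_lines: list[str]
    val_lines: list[str]


def make_random_splits(
    records: pd.DataFrame, train_fraction: float, n_cycles: int, seed: int
) -> list[CVSplit]:
    """Line-level random splits: a line's records move together."""
    lines = sorted(pd.unique(records["line"]))
    if len(lines) < 10:
        raise ValueError("need at least 10 lines for cross-validation")
    n_train = int(round(train_fraction * len(lines)))
    if len(lines) - n_train < 2:
        raise ValueError("train_fraction leaves fewer than 2 validation lines")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_cycles):
        perm = rng.permutation(len(lines))
        train = sorted(lines[i] for i in perm[:n_train])
        val = sorted(lines[i] for i in perm[n_train:])
        splits.append(CVSplit(train_lines=train, val_lines=val))
    return splits


def pearson_accuracy(observed, predicted) -> float:
    """Sample Pearson correlation; nan (flagged) for constant inputs."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size or obs.size < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.std(obs) < 1e-12 or np.std(pred) < 1e-12:
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


# ---------------------------------------------------------------------------
# model drivers (train on a record subset, predict target cells)
# ---------------------------------------------------------------------------

def _wide(records: pd.DataFrame) -> pd.DataFrame:
    return records.pivot_table(index=["environment", "line"], columns="trait", values="value")


def _predict_mcmc(records, grm, env, traits, train_lines, target_lines, settings):
    sub = records[(records["environment"] == env) & (records["line"].isin(train_lines))]
    samples = fit_mcmc_mixed(sub, grm, traits, settings=settings, environment=env)
    u = samples.mean("u")
    beta = samples.mean("beta")
    u_new = gblup_extend(u, grm, samples.line_ids, target_lines)
    return pd.DataFrame(u_new + beta, index=target_lines, columns=traits)


def _predict_bgge(records, grm, trait, holdout_cells, settings):
    rec = records[records["trait"] == trait].sort_values(["environment", "line"]).reset_index(drop=True)
    lines = rec["line"].tolist()
    envs = rec["environment"].tolist()
    kernels = build_ge_kernels(grm, lines, envs)
    key = list(zip(lines, envs))
    observed = np.array([k not in holdout_cells for k in key])
    samples = fit_bgge(
        rec["value"].to_numpy(),
        kernels,
        settings=settings,
        env_labels=envs,
        observed=observed,
    )
    rec = rec.assign(predicted=bgge_predictions(samples))
    return rec


def _predict_bmtme(records, grm, traits, holdout_cells, settings):
    rec = records.copy()
    key = list(zip(rec["line"], rec["environment"]))
    rec.loc[[k in holdout_cells for k in key], "value"] = np.nan
    samples = fit_bmtme(rec, grm, settings=settings, traits=traits, na_mode=True)
    return bmtme_predictions(samples)


def _predict_dl(records, grm, traits, holdout_cells, config):
    layout = records[["line", "environment"]].drop_duplicates().sort_values(["environment", "line"])
    design = build_design_matrices(layout)
    inputs = build_dl_inputs(design, grm)
    wide = _wide(records).reindex(
        pd.MultiIndex.from_frame(layout[["environment", "line"]])
    )[list(traits)]
    key = list(zip(layout["line"], layout["environment"]))
    test_mask = np.array([k in holdout_cells for k in key])
    train_mask = ~test_mask & ~wide.isna().any(axis=1).to_numpy()
    model = train_mlp(inputs.X[train_mask], wide.to_numpy()[train_mask], config)
    preds = predict_mlp(model, inputs.X)
    out = layout.reset_index(drop=True)
    return pd.concat(
        [out, pd.DataFrame(preds, columns=[f"pred_{t}" for t in traits])], axis=1
    )


# ---------------------------------------------------------------------------
# scenario I
# ---------------------------------------------------------------------------

def run_scenario_one(
    records: pd.DataFrame,
    grm: KinshipMatrix,
    models: list[str],
    approaches: list[str],
    scheme: CVScheme,
    settings: MCMCSettings | None = None,
    mlp_config: MLPConfig | None = None,
) -> pd.DataFrame:
    """Random-holdout cross-validation over models x approaches.

    Returns a tidy accuracy table with one row per
    (model, approach, environment, trait, cycle).
    """
    records = validate_phenotypes(records)
    for model in models:
        for app in approaches:
            if model not in MODEL_APPROACHES:
                raise ValueError(f"unknown model {model!r}")
            if app not in APPROACHES:
                raise ValueError(f"unknown approach {app!r}")
    pairs = [
        (model, app)
        for model in models
        for app in approaches
        if app in MODEL_APPROACHES[model]
    ]
    requested = {(m, a) for m in models for a in approaches}
    unsupported = requested - set(pairs)
    if len(models) == 1 and len(approaches) == 1 and unsupported:
        m, a = next(iter(unsupported))
        raise ValueError(f"model/approach pair ({m}, {a}) is not supported")

    settings = settings or MCMCSettings.tiny()
    mlp_config = mlp_config or MLPConfig(epochs=50)
    envs = sorted(records["environment"].unique())
    traits = sorted(records["trait"].unique())
    splits = make_random_splits(records, scheme.train_fraction, scheme.n_cycles, scheme.seed)
    obs_wide = _wide(records)
    seed_seq = np.random.SeedSequence(scheme.seed)

    rows = []
    for cycle, split in enumerate(splits, start=1):
        child = seed_seq.spawn(1)[0]
        fit_seed = int(child.generate_state(1)[0] % 2**31)
        cyc_settings = MCMCSettings(
            settings.n_iterations, settings.burn_in, settings.thin, seed=fit_seed
        )
        mlp_cfg = MLPConfig(**{**mlp_config.__dict__, "seed": fit_seed})
        for model, app in pairs:
            for env in envs:
                if scheme.full_line_holdout:
                    holdout = {(l, v) for l in split.val_lines for v in envs}
                else:
                    holdout = {(l, env) for l in split.val_lines}
                preds = _scenario_one_predictions(
                    records, grm, model, app, env, traits, split, holdout, cyc_settings, mlp_cfg
                )
                for trait in traits:
                    obs = [
                        obs_wide.loc[(env, l), trait]
                        for l in split.val_lines
                        if (env, l) in obs_wide.index
                    ]
                    pr = [
                        preds.get((l, trait), np.nan)
                        for l in split.val_lines
                        if (env, l) in obs_wide.index
                    ]
                    rows.append(
                        (model, app, env, trait, cycle, pearson_accuracy(obs, pr))
                    )
    return pd.DataFrame(
        rows, columns=["model", "approach", "environment", "trait", "cycle", "pearson_r"]
    )


def _scenario_one_predictions(
    records, grm, model, app, env, traits, split, holdout, settings, mlp_cfg
) -> dict:
    """Predictions for validation lines in ``env`` as {(line, trait): value}."""
    out = {}
    if model == "mcmc_mixed":
        use_traits = traits if app == "MTUE" else None
        if app == "UTUE":
            for trait in traits:
                df = _predict_mcmc(
                    records[records["trait"] == trait],
                    grm,
                    env,
                    [trait],
                    split.train_lines,
                    split.val_lines,
                    settings,
                )
                for l in split.val_lines:
                    out[(l, trait)] = df.loc[l, trait]
        else:  # MTUE
            df = _predict_mcmc(
                records, grm, env, traits, split.train_lines, split.val_lines, settings
            )
            for l in split.val_lines:
                for trait in traits:
                    out[(l, trait)] = df.loc[l, trait]
    elif model == "bgge":  # UTME
        for trait in traits:
            rec = _predict_bgge(records, grm, trait, holdout, settings)
            sub = rec[rec["environment"] == env].set_index("line")
            for l in split.val_lines:
                if l in sub.index:
                    out[(l, trait)] = sub.loc[l, "predicted"]
    elif model == "bmtme":  # MTME
        preds = _predict_bmtme(records, grm, traits, holdout, settings)
        sub = preds[preds["environment"] == env]
        for _, row in sub.iterrows():
            if row["line"] in split.val_lines:
                out[(row["line"], row["trait"])] = row["predicted"]
    elif model == "dl":
        if app in ("UTUE", "MTUE"):
            sub = records[records["environment"] == env]
            tlist = traits if app == "MTUE" else None
            for tset in ([traits] if app == "MTUE" else [[t] for t in traits]):
                preds = _predict_dl(sub, grm, tset, holdout, mlp_cfg)
                pr = preds[preds["environment"] == env].set_index("line")
                for l in split.val_lines:
                    if l in pr.index:
                        for trait in tset:
                            out[(l, trait)] = pr.loc[l, f"pred_{trait}"]
        else:  # UTME / MTME over all environments
            for tset in ([traits] if app == "MTME" else [[t] for t in traits]):
                preds = _predict_dl(records, grm, tset, holdout, mlp_cfg)
                pr = preds[preds["environment"] == env].set_index("line")
                for l in split.val_lines:
                    if l in pr.index:
                        for trait in tset:
                            out[(l, trait)] = pr.loc[l, f"pred_{trait}"]
    else:  # pragma: no cover
        raise ValueError(f"unknown model {model!r}")
    return out


# ---------------------------------------------------------------------------
# scenario II
# ---------------------------------------------------------------------------

def run_scenario_two(
    records: pd.DataFrame,
    grm: KinshipMatrix,
    models: list[str],
    training_set_id: str,
    training_sets: dict,
    target_environment: str,
    settings: MCMCSettings | None = None,
    mlp_config: MLPConfig | None = None,
) -> pd.DataFrame:
    """Forward prediction of a held-out environment.

    ``training_sets`` maps DT ids to environment lists, e.g.
    ``{"DT1": ["E3"], "DT2": ["E1", "E2"], "DT3": ["E1", "E2", "E3"]}``.
    DT1 (a single environment) uses the uni-environment models via genotype
    effect transfer; DT2/DT3 use the multi-environment models with the
    target environment's cells treated as unobserved.
    """
    records = validate_phenotypes(records)
    if training_set_id not in training_sets:
        raise ValueError(f"unknown training set {training_set_id!r}")
    train_envs = list(training_sets[training_set_id])
    if target_environment in train_envs:
        raise ValueError("target environment overlaps the training set")
    settings = settings or MCMCSettings.tiny()
    mlp_config = mlp_config or MLPConfig(epochs=50)
    traits = sorted(records["trait"].unique())
    obs_wide = _wide(records)
    target_lines = sorted(
        records.loc[records["environment"] == target_environment, "line"].unique()
    )
    single_env = len(train_envs) == 1
    use = records[records["environment"].isin(train_envs + [target_environment])]
    holdout = {(l, target_environment) for l in target_lines}

    rows = []
    for model in models:
        approaches = (
            [a for a in MODEL_APPROACHES[model] if a.endswith("UE")]
            if single_env
            else [a for a in MODEL_APPROACHES[model] if a.endswith("ME")]
        )
        for app in sorted(approaches):
            preds: dict = {}
            if model == "mcmc_mixed":
                env = train_envs[0]
                tsets = [traits] if app == "MTUE" else [[t] for t in traits]
                for tset in tsets:
                    df = _predict_mcmc(
                        use if app == "MTUE" else use[use["trait"].isin(tset)],
                        grm,
                        env,
                        tset,
                        sorted(use.loc[use["environment"] == env, "line"].unique()),
                        target_lines,
                        settings,
                    )
                    for l in target_lines:
                        for trait in tset:
                            preds[(l, trait)] = df.loc[l, trait]
            elif model == "bgge":
                for trait in traits:
                    rec = _predict_bgge(use, grm, trait, holdout, settings)
                    sub = rec[rec["environment"] == target_environment].set_index("line")
                    for l in target_lines:
                        if l in sub.index:
                            preds[(l, trait)] = sub.loc[l, "predicted"]
            elif model == "bmtme":
                df = _predict_bmtme(use, grm, traits, holdout, settings)
                sub = df[df["environment"] == target_environment]
                for _, row in sub.iterrows():
                    preds[(row["line"], row["trait"])] = row["predicted"]
            elif model == "dl":
                src = use[use["environment"] == train_envs[0]] if single_env else use
                if single_env:
                    # train in the single environment, transfer to the target
                    tsets = [traits] if app == "MTUE" else [[t] for t in traits]
                    for tset in tsets:
                        pr = _predict_dl(src, grm, tset, set(), mlp_config)
                        pr = pr.set_index("line")
                        for l in target_lines:
                            if l in pr.index:
                                for trait in tset:
                                    preds[(l, trait)] = pr.loc[l, f"pred_{trait}"]
                else:
                    tsets = [traits] if app == "MTME" else [[t] for t in traits]
                    for tset in tsets:
                        pr = _predict_dl(use, grm, tset, holdout, mlp_config)
                        sub = pr[pr["environment"] == target_environment].set_index("line")
                        for l in target_lines:
                            if l in sub.index:
                                for trait in tset:
                                    preds[(l, trait)] = sub.loc[l, f"pred_{trait}"]
            for trait in traits:
                obs, pr = [], []
                for l in target_lines:
                    if (target_environment, l) in obs_wide.index and (l, trait) in preds:
                        obs.append(obs_wide.loc[(target_environment, l), trait])
                        pr.append(preds[(l, trait)])
                rows.append(
                    (
                        model,
                        app,
                        training_set_id,
                        target_environment,
                        trait,
                        1,
                        pearson_accuracy(obs, pr),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "model",
            "approach",
            "training_set",
            "environment",
            "trait",
            "cycle",
            "pearson_r",
        ],
    )


# ---------------------------------------------------------------------------
# aggregation and comparison
# ---------------------------------------------------------------------------

def summarize_accuracy(table: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy over cycles per model x approach x environment x trait."""
    return (
        table.groupby(["model", "approach", "environment", "trait"], as_index=False)[
            "pearson_r"
        ]
        .mean()
        .rename(columns={"pearson_r": "mean_pearson_r"})
    )


def relative_improvement(
    table: pd.DataFrame, baseline_selector: dict, comparison_selector: dict
) -> float:
    """Percent change in mean accuracy between two selections.

    Means are taken over the (environment, trait) cells present in both
    selections; the result is 100 * (comparison - baseline) / baseline.
    """

    def _cells(sel):
        sub = table.copy()
        for k, v in sel.items():
            sub = sub[sub[k] == v]
        if sub.empty:
            raise ValueError(f"selector {sel} matches no rows")
        return sub.groupby(["environment", "trait"])["pearson_r"].mean()

    base = _cells(baseline_selector)
    comp = _cells(comparison_selector)
    common = base.index.intersection(comp.index)
    if common.empty:
        raise ValueError("selections share no (environment, trait) cells")
    mb = float(base.loc[common].mean())
    mc = float(comp.loc[common].mean())
    return 100.0 * (mc - mb) / mb


def compare_models(table: pd.DataFrame, cell: dict, alpha: float = 0.01) -> dict:
    """Tukey-Kramer grouping letters for per-cycle accuracies within a cell.

    Models with fewer than 2 cycles are excluded.  Models sharing a letter
    are not significantly different at ``alpha``.
    """
    sub = table.copy()
    for k, v in cell.items():
        sub = sub[sub[k] == v]
    counts = sub.groupby("model")["pearson_r"].count()
    excluded = counts[counts < 2].index.tolist()
    sub = sub[~sub["model"].isin(excluded)]
    models = sorted(sub["model"].unique())
    if len(models) < 2:
        raise ValueError("need at least 2 models with >= 2 cycles each")

    means = sub.groupby("model")["pearson_r"].mean()
    if sub.groupby("model")["pearson_r"].var().max() < 1e-20:
        # identical cycle vectors: no separation possible
        return {m: "a" for m in models}
    res = pairwise_tukeyhsd(
        sub["pearson_r"].to_numpy(), sub["model"].to_numpy(), alpha=alpha
    )
    groups = [str(gp) for gp in res.groupsunique]
    different = {
        frozenset((groups[i], groups[j]))
        for (i, j), rej in zip(combinations(range(len(groups)), 2), res.reject)
        if rej
    }
    return _compact_letters(sorted(models, key=lambda m: -means[m]), different)


def _compact_letters(ordered_models: list[str], different: set) -> dict:
    """Insert-and-absorb compact letter display from pairwise differences."""
    groups: list[set] = []
    for m in ordered_models:
        placed = False
        for grp in groups:
            if all(frozenset((m, other)) not in different for other in grp):
                grp.add(m)
                placed = True
        if not placed:
            groups.append({m})
    # absorb redundant groups
    groups = [g for i, g in enumerate(groups) if not any(g < h for j, h in enumerate(groups) if i != j)]
    letters = {m: "" for m in ordered_models}
    for letter, grp in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for m in sorted(grp, key=ordered_models.index):
            letters[m] += letter
    return letters


def pivot_accuracy_table(table: pd.DataFrame) -> pd.DataFrame:
    """Environment x trait rows with model/approach columns of mean accuracy."""
    summary = summarize_accuracy(table)
    summary["column"] = summary["model"] + ":" + summary["approach"]
    return summary.pivot(index=["environment", "trait"], columns="column", values="mean_pearson_r")
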