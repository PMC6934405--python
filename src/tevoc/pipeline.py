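"""Study orchestration: group assignment, descriptives, and group x test models.

The pipeline mirrors a three-group pre/post training design: subjects
are assigned to balanced groups from their second pretraining
identification score, thresholds and relative information transfer are
computed per subject and session, and outcomes are modelled with group
(control / AMD-trained / AMR-trained) and test (pretest / posttest)
fixed effects plus their interaction, with control and pretest as
reference levels.

Estimation is delegated: continuous outcomes go to a linear
mixed-effects model (random intercept per subject, plus a random slope
for test when it converges); binary trial-level outcomes go to
generalized estimating equations with an exchangeable within-subject
correlation, the standard frequentist treatment of correlated binary
responses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .confusion import it_table
from .observer import GROUPS, StudyDesign, StudyData, generate_study
from .psychofit import threshold_table

__all__ = [
    "GroupAssignment",
    "ModelSpec",
    "ModelFit",
    "assign_groups",
    "descriptives",
    "fit_model",
    "pre_post_contrasts",
    "run_pipeline",
]


@dataclass(frozen=True)
class GroupAssignment:
    assignment: dict            # subject -> group
    scores: dict                # subject -> balancing score (% correct)
    group_means: dict           # group -> mean score
    balanced: bool
    tolerance: float

    def sizes(self) -> dict:
        sizes = {g: 0 for g in set(self.assignment.values())}
        for g in self.assignment.values():
            sizes[g] += 1
        return sizes


def assign_groups(scores, groups=GROUPS, tolerance: float = 5.0) -> GroupAssignment:
    """Sequentially assign subjects to groups balancing a baseline score.

    *scores* maps subject -> pretraining-2 percent correct (a dict or
    Series; insertion order is the arrival order).  Each subject is
    pre-assigned round-robin; if their score falls below the lowest
    current group mean they are moved to the group with the highest
    mean, if above the highest mean to the group with the lowest mean,
    subject to per-group capacity ``len(scores) / len(groups)`` so group
    sizes never change.  A warning (and ``balanced=False``) is issued if
    the final pairwise gap between group means exceeds *tolerance*
    percentage points.
    """
    scores = dict(scores)
    n = len(scores)
    if n % len(groups) != 0:
        raise ValueError(f"{n} subjects cannot split evenly into {len(groups)} groups")
    capacity = n // len(groups)
    members: dict[str, list] = {g: [] for g in groups}
    assignment: dict = {}

    def mean(g):
        return float(np.mean([scores[s] for s in members[g]]))

    for i, (subject, score) in enumerate(scores.items()):
        pre = groups[i % len(groups)]
        nonempty = [g for g in groups if members[g]]
        target = pre
        if len(nonempty) == len(groups):
            means = {g: mean(g) for g in groups}
            if score < min(means.values()):
                target = max(means, key=means.get)
            elif score > max(means.values()):
                target = min(means, key=means.get)
        if len(members[target]) >= capacity:
            open_groups = [g for g in groups if len(members[g]) < capacity]
            if members and all(members[g] for g in open_groups):
                means = {g: mean(g) for g in open_groups}
                target = (max(means, key=means.get) if score < np.median(list(scores.values()))
                          else min(means, key=means.get))
            else:
                target = open_groups[0]
        members[target].append(subject)
        assignment[subject] = target

    group_means = {g: mean(g) for g in groups}
    gap = max(group_means.values()) - min(group_means.values())
    balanced = gap <= tolerance
    if not balanced:
        warnings.warn(f"group means differ by {gap:.1f} points (> {tolerance}); "
                      "best-effort assignment returned", stacklevel=2)
    return GroupAssignment(assignment=assignment, scores=scores,
                           group_means=group_means, balanced=balanced,
                           tolerance=tolerance)


def descriptives(records: pd.DataFrame, value: str,
                 by=("group", "session"), ci: float = 0.95) -> pd.DataFrame:
    """Mean, SD and t-based confidence interval per cell.

    Statistics are computed at the row (trial or subject) level of
    *records*; binary 0/100 outcomes therefore yield SDs near 50.
    """
    rows = []
    for keys, cell in records.groupby(list(by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        v = cell[value].to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError(f"cell {keys} has fewer than 2 records")
        m, sd = float(v.mean()), float(v.std(ddof=1))
        half = stats.t.ppf(0.5 + ci / 2, v.size - 1) * sd / np.sqrt(v.size)
        rows.append(dict(zip(by, keys)) | {
            "n": v.size, "mean": m, "sd": sd,
            "ci_lo": m - half, "ci_hi": m + half,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ModelSpec:
    """Contract for a group x test model.

    ``outcome``: response column.  ``family``: "linear" (mixed model) or
    "binomial" (GEE logit).  ``controls``: additive fixed covariates
    (e.g. block, centred trial order).  ``extra_factors``: additional
    fully-crossed fixed factors (e.g. phonetic feature for relative IT).
    """

    outcome: str
    family: str = "linear"
    fixed: tuple[str, ...] = ("group", "test")
    controls: tuple[str, ...] = ()
    extra_factors: tuple[str, ...] = ()
    group_col: str = "group"
    test_col: str = "test"
    subject_col: str = "subject"

    def __post_init__(self) -> None:
        if self.family not in ("linear", "binomial"):
            raise ValueError(f"unknown family: {self.family!r}")

    def formula(self) -> str:
        factors = [f"C({self.group_col}, Treatment('control'))",
                   f"C({self.test_col}, Treatment('pretest'))"]
        factors += [f"C({f})" for f in self.extra_factors]
        rhs = " * ".join(factors)
        for ctl in self.controls:
            rhs += f" + {ctl}"
        return f"{self.outcome} ~ {rhs}"


@dataclass(frozen=True)
class ModelFit:
    spec: ModelSpec
    effects: pd.DataFrame        # term, estimate, se, ci_lo, ci_hi, stat, p
    converged: bool
    backend: str
    random_structure: str
    result: object = field(repr=False, default=None)


def _effect_table(result) -> pd.DataFrame:
    params = result.params
    if hasattr(result, "fe_params"):        # MixedLM: fixed effects only
        names = list(result.fe_params.index)
    else:
        names = list(params.index)
    conf = result.conf_int()
    rows = []
    for name in names:
        rows.append({
            "term": name,
            "estimate": float(params[name]),
            "se": float(result.bse[name]),
            "ci_lo": float(conf.loc[name, 0]),
            "ci_hi": float(conf.loc[name, 1]),
            "stat": float(result.tvalues[name]),
            "p": float(result.pvalues[name]),
        })
    return pd.DataFrame(rows)


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit the group x test model, delegating to statsmodels.

    Linear family: MixedLM with a by-subject random intercept and a
    random slope for test; if that structure fails to converge it is
    simplified to intercept-only (recorded in ``random_structure``).
    Binomial family: GEE logit with exchangeable within-subject
    correlation (population-averaged estimates, robust SEs).
    """
    data = data.dropna(subset=[spec.outcome]).copy()
    formula = spec.formula()
    if spec.family == "linear":
        structures = [f"0 + C({spec.test_col})", "1"]
        last_err = None
        for re_formula in structures:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = smf.mixedlm(formula, data, groups=data[spec.subject_col],
                                        re_formula=re_formula)
                    result = model.fit(reml=True, method="lbfgs")
                if result.converged:
                    return ModelFit(spec, _effect_table(result), True, "MixedLM",
                                    re_formula, result)
            except Exception as err:  # singular fits, LinAlgError
                last_err = err
        raise RuntimeError(f"mixed model failed to converge under all random "
                           f"structures tried ({structures}): {last_err}")
    # binomial
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.gee(formula, groups=data[spec.subject_col], data=data,
                        family=sm.families.Binomial(),
                        cov_struct=sm.cov_struct.Exchangeable())
        result = model.fit()
    return ModelFit(spec, _effect_table(result), True, "GEE-logit",
                    "exchangeable", result)


def _find_term(terms, *needles):
    hits = [t for t in terms if all(n in t for n in needles)]
    return hits[0] if hits else None


def pre_post_contrasts(fit: ModelFit, groups=GROUPS, ci: float = 0.95) -> pd.DataFrame:
    """Per-group pretest→posttest estimates and between-group differences.

    Built as linear contrasts of the fixed effects: the reference
    group's improvement is the test main effect; each trained group adds
    its group x test interaction.  Positive estimates mean the outcome
    rose at posttest (for log10 thresholds, improvement is a *negative*
    estimate).
    """
    result = fit.result
    names = (list(result.fe_params.index) if hasattr(result, "fe_params")
             else list(result.params.index))
    test_term = _find_term(names, "posttest")
    if test_term is None or ":" not in "".join(names):
        if test_term is None:
            raise ValueError("model does not contain a test effect")

    def contrast_vector(terms_with_sign):
        L = np.zeros((1, len(names)))
        for term, sign in terms_with_sign:
            L[0, names.index(term)] = sign
        return L

    z = stats.norm.ppf(0.5 + ci / 2)
    rows = []
    vectors = {}
    for g in groups:
        terms = [(test_term, 1.0)]
        if g != groups[0]:
            inter = _find_term(names, g, "posttest", ":")
            if inter is None:
                raise ValueError(f"missing group x test interaction for {g}")
            terms.append((inter, 1.0))
        vectors[g] = contrast_vector(terms)
    def one(label, L):
        tt = result.t_test(L)
        est = float(np.squeeze(tt.effect))
        se = float(np.squeeze(tt.sd))
        rows.append({"contrast": label, "estimate": est, "se": se,
                     "ci_lo": est - z * se, "ci_hi": est + z * se,
                     "stat": float(np.squeeze(tt.tvalue)),
                     "p": float(np.squeeze(tt.pvalue))})

    for g in groups:
        one(f"{g}: post - pre", vectors[g])
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            one(f"({g2} - {g1}): post - pre", vectors[g2] - vectors[g1])
    return pd.DataFrame(rows)


def run_pipeline(design: StudyDesign = StudyDesign(), outdir=None,
                 study: StudyData | None = None) -> dict:
    """End-to-end synthetic study: generate, fit thresholds, score IT, model.

    Returns a dict of DataFrames (and writes CSVs plus a JSON-lines log
    under *outdir* when given).  Steps: synthetic study generation →
    per-track psychometric thresholds with QC and outlier flags → group
    assignment check on pretraining-2 scores → relative IT per subject,
    session and feature → group x test models for each task's threshold,
    trial-level identification accuracy, and relative IT.
    """
    log: list[dict] = []
    if study is None:
        study = generate_study(design)
    log.append({"step": "generate", "subjects": len(study.subjects),
                "track_trials": len(study.tracks), "vcv_trials": len(study.vcv_trials)})

    thresholds = threshold_table(study.tracks)
    n_invalid = int((~thresholds["valid"]).sum())
    log.append({"step": "psychofit", "tracks": len(thresholds),
                "discarded": n_invalid,
                "discard_fraction": n_invalid / len(thresholds),
                "outliers": int(thresholds["outlier"].sum())})

    p2 = study.vcv_trials.query("session == 'pretraining2'")
    scores = (p2.groupby("subject", sort=False)["correct"].mean() * 100).to_dict()
    balance = assign_groups(scores)
    log.append({"step": "assign", "group_means": balance.group_means,
                "balanced": balance.balanced})

    test_vcv = study.vcv_trials[study.vcv_trials["session"].isin(["pretest", "posttest"])]
    it = it_table(test_vcv, by=("subject", "group", "session"))
    log.append({"step": "confusion_it", "cells": len(it)})

    usable = thresholds[thresholds["valid"] & ~thresholds["outlier"]].copy()
    usable = usable.rename(columns={"session": "test"})
    models: dict[str, ModelFit] = {}
    contrasts = {}
    for task, cell in usable.groupby("task"):
        spec = ModelSpec(outcome="threshold_log10", family="linear",
                         controls=("block",))
        fitres = fit_model(spec, cell)
        models[f"threshold_{task}"] = fitres
        contrasts[f"threshold_{task}"] = pre_post_contrasts(fitres)
        log.append({"step": "fit", "outcome": f"threshold_{task}",
                    "backend": fitres.backend,
                    "random_structure": fitres.random_structure})

    vcv = test_vcv.rename(columns={"session": "test"}).copy()
    vcv["trial_order_c"] = vcv["trial_order"] - vcv["trial_order"].mean()
    spec = ModelSpec(outcome="correct", family="binomial",
                     controls=("trial_order_c",))
    fitres = fit_model(spec, vcv)
    models["vcv_accuracy"] = fitres
    contrasts["vcv_accuracy"] = pre_post_contrasts(fitres)
    log.append({"step": "fit", "outcome": "vcv_accuracy", "backend": fitres.backend})

    it_model_data = it.rename(columns={"session": "test"})
    spec = ModelSpec(outcome="relative_it", family="linear",
                     extra_factors=("feature",))
    fitres = fit_model(spec, it_model_data)
    models["relative_it"] = fitres
    contrasts["relative_it"] = pre_post_contrasts(fitres)
    log.append({"step": "fit", "outcome": "relative_it", "backend": fitres.backend})

    out = {"study": study, "thresholds": thresholds, "it": it,
           "assignment": balance, "models": models, "contrasts": contrasts,
           "log": log}
    if outdir is not None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        study.write(outdir)
        thresholds.to_csv(outdir / "thresholds.csv", index=False)
        it.to_csv(outdir / "it_results.csv", index=False)
        for name, fitres in models.items():
            fitres.effects.to_csv(outdir / f"effects_{name}.csv", index=False)
            contrasts[name].to_csv(outdir / f"contrasts_{name}.csv", index=False)
        with open(outdir / "pipeline_log.jsonl", "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    return out
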