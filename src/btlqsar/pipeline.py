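"""End-to-end modelling and screening driver.

``run_modeling_pipeline`` reproduces the study design on any descriptor/
activity table (in practice the synthetic BTL-like data): descriptor
filtering, dataset splitting, GA descriptor selection, training of a battery
of three classification models —

* ``nnc`` — counter-propagation network on the full filtered pool,
  60/25/15 train/test/validation split;
* ``nnd`` — counter-propagation network on a GA-reduced subset, 75/25;
* ``qd``  — multiple linear regression classifier on a GA-reduced subset,
  75/25;

plus four GA-optimized counter-propagation *regression* models (``M1``–``M4``,
trained on the active compounds only) whose responses are combined by
inverse-leverage consensus.  ``run_screening`` applies a trained battery to
an untested compound set and emits per-compound transporter-activity
profiles: per-model calls with applicability-domain flags, consensus calls,
and a consensus pKi estimate for compounds called active by at least one
classification model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as cns
from . import cpann as _cpann
from . import ga as _ga
from . import mlr as _mlr
from . import preprocess as prep
from .data import ACTIVE, INACTIVE, ActivityTable, DescriptorMatrix

PAIR_MODES = {
    "NN-C+NN-D": ("nnc", "nnd"),
    "NN-C+Q-D": ("nnc", "qd"),
    "NN-D+Q-D": ("nnd", "qd"),
}

TABLE1_ROWS = ["TP", "TN", "FP", "FN", "sum", "PR", "SE", "SP", "ACC", "NPV", "PPV", "MCC"]


@dataclass
class PipelineOptions:
    """Tunable knobs of the modelling pipeline (defaults mirror the study
    design; sizes of the stochastic searches are kept modest so a full run
    stays interactive)."""

    correlation_threshold: float = 0.9
    kohonen_pool: int | None = None  # None: skip the similarity reduction
    split_method: str = "random"
    three_way_fractions: tuple = (0.60, 0.25, 0.15)
    two_way_fractions: tuple = (0.75, 0.25)
    # classification maps are kept a bit coarser than one-neuron-per-compound
    # so the ED_crt applicability domain spans the training neighbourhood
    # instead of collapsing onto memorized training points
    cpann_classification: _cpann.CpannConfig = field(
        default_factory=lambda: _cpann.CpannConfig(grid_rows=7, grid_cols=7, epochs=80)
    )
    cpann_regression: _cpann.CpannConfig = field(
        default_factory=lambda: _cpann.CpannConfig(
            grid_rows=7, grid_cols=7, epochs=120, eta_max=0.8, eta_min=0.05
        )
    )
    ga_classification: _ga.GaConfig = field(
        default_factory=lambda: _ga.GaConfig(
            population_size=16, generations=8, subset_min=5, subset_max=18, cv_folds=3
        )
    )
    # regression masks are searched with the fast MLR cross-validated fitness
    # (a reliable proxy on the mostly linear response of the small active
    # subset); the final models trained on the winning masks are CP-ANNs
    ga_regression: _ga.GaConfig = field(
        default_factory=lambda: _ga.GaConfig(
            population_size=20, generations=10, subset_min=4, subset_max=10, cv_folds=4
        )
    )
    ga_cv_cpann: _cpann.CpannConfig = field(
        default_factory=lambda: _cpann.CpannConfig(grid_rows=6, grid_cols=6, epochs=30)
    )
    n_regression_models: int = 4


@dataclass
class Battery:
    """A trained model battery with its provenance."""

    descriptor_pool: list[str]
    split_three: prep.DatasetSplit
    split_two: prep.DatasetSplit
    split_regression: prep.DatasetSplit
    classification_models: dict  # name -> CpannModel | MlrModel
    classification_masks: dict  # name -> list of descriptor names
    regression_models: dict  # name -> CpannModel
    regression_masks: dict  # name -> list of descriptor names
    regression_leverage: dict  # name -> LeverageMap
    seed: int

    def model_names(self) -> list[str]:
        return list(self.classification_models)

    # -- serialization -------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format": "btlqsar-battery",
            "version": 1,
            "seed": self.seed,
            "descriptor_pool": self.descriptor_pool,
            "split_three": json.loads(self.split_three.to_json()),
            "split_two": json.loads(self.split_two.to_json()),
            "split_regression": json.loads(self.split_regression.to_json()),
            "classification_models": {
                k: json.loads(m.to_json()) for k, m in self.classification_models.items()
            },
            "classification_masks": self.classification_masks,
            "regression_models": {
                k: json.loads(m.to_json()) for k, m in self.regression_models.items()
            },
            "regression_masks": self.regression_masks,
            "regression_leverage": {
                k: {
                    "descriptor_names": lm.descriptor_names,
                    "scaling": lm.scaling.to_dict(),
                    "xtx_inverse": lm.xtx_inverse.tolist(),
                    "hat_star": lm.hat_star,
                    "n_train": lm.n_train,
                }
                for k, lm in self.regression_leverage.items()
            },
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Battery":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        if d.get("format") != "btlqsar-battery":
            raise ValueError("not a battery file")
        from .data import ScalingParams

        def load_model(md):
            if md["format"] == _cpann.FORMAT_TAG:
                return _cpann.CpannModel.from_json(json.dumps(md))
            if md["format"] == _mlr.FORMAT_TAG:
                return _mlr.MlrModel.from_json(json.dumps(md))
            raise ValueError(f"unknown model format {md['format']!r}")

        return cls(
            descriptor_pool=list(d["descriptor_pool"]),
            split_three=prep.DatasetSplit.from_json(json.dumps(d["split_three"])),
            split_two=prep.DatasetSplit.from_json(json.dumps(d["split_two"])),
            split_regression=prep.DatasetSplit.from_json(json.dumps(d["split_regression"])),
            classification_models={k: load_model(m) for k, m in d["classification_models"].items()},
            classification_masks={k: list(v) for k, v in d["classification_masks"].items()},
            regression_models={k: load_model(m) for k, m in d["regression_models"].items()},
            regression_masks={k: list(v) for k, v in d["regression_masks"].items()},
            regression_leverage={
                k: _mlr.LeverageMap(
                    descriptor_names=list(v["descriptor_names"]),
                    scaling=ScalingParams.from_dict(v["scaling"]),
                    xtx_inverse=np.asarray(v["xtx_inverse"]),
                    hat_star=float(v["hat_star"]),
                    n_train=int(v["n_train"]),
                )
                for k, v in d["regression_leverage"].items()
            },
            seed=int(d["seed"]),
        )

    def sha256(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _classification_labels(battery: Battery, X: DescriptorMatrix) -> pd.DataFrame:
    """Per-model label / ad_flag frames for arbitrary compounds."""
    frames = {}
    for name, model in battery.classification_models.items():
        sub = X.select_descriptors(battery.classification_masks[name])
        if isinstance(model, _mlr.MlrModel):
            pred = _mlr.predict_mlr(model, sub, classification_cut=0.5)
        else:
            pred = _cpann.predict_cpann(model, sub)
        frames[name] = pred[["label", "ad_flag", "raw"]]
    return frames


def run_modeling_pipeline(
    descriptors: DescriptorMatrix,
    activities: ActivityTable,
    seed: int = 0,
    options: PipelineOptions | None = None,
) -> tuple[Battery, dict]:
    """Train the full classification + regression battery.

    Returns the battery and a report dict with the preprocessing trace, the
    per-model training/validation quality indicators, the consensus quality
    table (confusion-count rows × model/consensus columns over the modeling
    set) and the external regression statistics of M1–M4 and their consensus.
    """
    if options is None:
        options = PipelineOptions()
    opt = options

    # --- descriptor treatment ------------------------------------------------
    X0 = prep.drop_zero_variance(descriptors)
    X1 = prep.drop_intercorrelated(X0, opt.correlation_threshold)
    if opt.kohonen_pool is not None:
        pool = prep.kohonen_reduce(X1, target_pool=opt.kohonen_pool, seed=seed)
        X1 = X1.select_descriptors(pool)
    trace = {
        "n_input_descriptors": descriptors.n_descriptors,
        "n_after_zero_variance": X0.n_descriptors,
        "n_after_intercorrelation": X1.n_descriptors,
        "pool": list(X1.names),
    }
    y01 = activities.binary()

    # --- splits --------------------------------------------------------------
    split3 = prep.split_dataset(X1, activities, opt.three_way_fractions,
                                opt.split_method, seed)
    split2 = prep.split_dataset(X1, activities, opt.two_way_fractions,
                                opt.split_method, seed + 1)

    # --- classification models ----------------------------------------------
    models: dict = {}
    masks: dict = {}

    def subset(ids, names):
        return X1.select_compounds(ids).select_descriptors(names)

    # nnc: full pool, 3-way split
    cfg_nnc = _cpann.CpannConfig(**{**asdict(opt.cpann_classification), "seed": seed})
    ids3 = split3.train_ids
    y3 = activities.select_compounds(ids3).binary()
    models["nnc"] = _cpann.train_cpann(subset(ids3, X1.names), y3, cfg_nnc)
    masks["nnc"] = list(X1.names)

    # nnd: GA-reduced CP-ANN, 75/25 split
    ids2 = split2.train_ids
    Xtr2 = X1.select_compounds(ids2)
    y2 = activities.select_compounds(ids2).binary()
    ga_cls = _ga.GaConfig(**{**asdict(opt.ga_classification), "seed": seed})
    ga_nnd = _ga.ga_search(Xtr2, y2, model_type="cpann", ga=ga_cls,
                           task="classification",
                           cpann_config=_cpann.CpannConfig(
                               **{**asdict(opt.ga_cv_cpann), "seed": seed}))
    masks["nnd"] = ga_nnd.selected_names
    cfg_nnd = _cpann.CpannConfig(**{**asdict(opt.cpann_classification), "seed": seed + 1})
    models["nnd"] = _cpann.train_cpann(subset(ids2, masks["nnd"]), y2, cfg_nnd)

    # qd: GA-reduced MLR classifier, same 75/25 split
    ga_qd_cfg = _ga.GaConfig(**{**asdict(opt.ga_classification),
                                "seed": seed + 1, "subset_max": 11})
    ga_qd = _ga.ga_search(Xtr2, y2, model_type="mlr", ga=ga_qd_cfg,
                          task="classification")
    masks["qd"] = ga_qd.selected_names
    models["qd"] = _mlr.fit_mlr(subset(ids2, masks["qd"]), y2)

    # --- regression models on actives only ----------------------------------
    active_ids = [i for i, lab in zip(activities.ids, activities.labels) if lab == ACTIVE]
    Xact = X1.select_compounds(active_ids)
    yact_tab = activities.select_compounds(active_ids)
    split_reg = prep.split_dataset(Xact, yact_tab, opt.two_way_fractions,
                                   "random", seed + 2)
    Xreg_tr = Xact.select_compounds(split_reg.train_ids)
    yreg_tr = yact_tab.select_compounds(split_reg.train_ids).pki

    reg_models: dict = {}
    reg_masks: dict = {}
    reg_lev: dict = {}
    for k in range(opt.n_regression_models):
        name = f"M{k + 1}"
        ga_cfg = _ga.GaConfig(**{**asdict(opt.ga_regression), "seed": seed + 10 + k})
        res = _ga.ga_search(Xreg_tr, yreg_tr, model_type="mlr", ga=ga_cfg,
                            task="regression")
        reg_masks[name] = res.selected_names
        cfg = _cpann.CpannConfig(**{**asdict(opt.cpann_regression),
                                    "seed": seed + 10 + k})
        Xsub = Xreg_tr.select_descriptors(res.selected_names)
        reg_models[name] = _cpann.train_cpann(Xsub, yreg_tr, cfg, task="regression")
        reg_lev[name] = _mlr.LeverageMap.from_training(Xsub)

    battery = Battery(
        descriptor_pool=list(X1.names),
        split_three=split3,
        split_two=split2,
        split_regression=split_reg,
        classification_models=models,
        classification_masks=masks,
        regression_models=reg_models,
        regression_masks=reg_masks,
        regression_leverage=reg_lev,
        seed=seed,
    )

    report = {
        "preprocess": trace,
        "classification": classification_report(battery, X1, activities),
        "regression": regression_report(battery, Xact, yact_tab),
        "ga": {
            "nnd": {"fitness": ga_nnd.best_fitness, "n_selected": len(masks["nnd"])},
            "qd": {"fitness": ga_qd.best_fitness, "n_selected": len(masks["qd"])},
        },
    }
    return battery, report


def classification_report(
    battery: Battery, X: DescriptorMatrix, activities: ActivityTable
) -> dict:
    """Quality-indicator table over the modeling set plus per-model
    training/validation accuracies.

    Single models predict every offered compound (their in-domain fraction
    is reported separately); in the consensus columns an out-of-domain model
    abstains, so consensus coverage (the Σ row) shrinks with strictness.
    """
    from . import metrics as mx

    frames = _classification_labels(battery, X)
    y_true = list(activities.labels)
    ids = X.ids

    columns: dict[str, list] = {}
    in_ad_fraction: dict[str, float] = {}
    for name, fr in frames.items():
        columns[_display(name)] = list(fr["label"])
        in_ad_fraction[_display(name)] = float(fr["ad_flag"].mean())

    # AD-gated votes for consensus columns
    votes = {
        name: [
            lab if ok else None
            for lab, ok in zip(frames[name]["label"], frames[name]["ad_flag"])
        ]
        for name in frames
    }
    for label, (a, b) in PAIR_MODES.items():
        columns[label] = [
            cns.consensus_classify([votes[a][i], votes[b][i]], "pairwise").combined_label
            for i in range(len(ids))
        ]
    triples = [
        [votes["nnc"][i], votes["nnd"][i], votes["qd"][i]] for i in range(len(ids))
    ]
    verdicts_strict = [cns.consensus_classify(t, "strict") for t in triples]
    verdicts_ab = [cns.consensus_classify(t, "A+B") for t in triples]
    columns["A"] = [v.combined_label for v in verdicts_strict]
    columns["B"] = [
        v.combined_label if v.agreement_type == "B" else cns.NO_PREDICTION
        for v in verdicts_ab
    ]
    columns["A+B"] = [v.combined_label for v in verdicts_ab]

    table = {}
    for col, labels in columns.items():
        preds = [lab if lab in (ACTIVE, INACTIVE) else None for lab in labels]
        cc = mx.confusion(y_true, preds, n_total=len(ids))
        q = mx.quality_indicators(cc)
        table[col] = {
            "TP": cc.tp, "TN": cc.tn, "FP": cc.fp, "FN": cc.fn,
            "sum": cc.n_predicted, "PR": q.pr, "SE": q.se, "SP": q.sp,
            "ACC": q.acc_standard, "ACC_balanced": q.acc_balanced,
            "NPV": q.npv, "PPV": q.ppv, "MCC": q.mcc,
        }

    # battery-level external check: consensus accuracy over the shared
    # 75/25 validation compounds (external to nnd and qd)
    val_ids = battery.split_two.validation_ids
    val_pos = [ids.index(i) for i in val_ids]
    val_truth = activities.select_compounds(val_ids).labels
    validation = {}
    for col in ("A", "A+B", *PAIR_MODES):
        labs = [columns[col][i] for i in val_pos]
        pairs = [(p, t) for p, t in zip(labs, val_truth) if p in (ACTIVE, INACTIVE)]
        validation[col] = {
            "acc": float(np.mean([p == t for p, t in pairs])) if pairs else float("nan"),
            "coverage": len(pairs) / len(val_ids),
        }

    # per-model accuracy on own training / validation partitions
    per_model = {}
    for name, fr in frames.items():
        split = battery.split_three if name == "nnc" else battery.split_two
        for part, part_ids in (("train", split.train_ids),
                               ("validation", split.validation_ids)):
            truth = activities.select_compounds(part_ids)
            pred = fr.loc[part_ids, "label"]
            acc = float(np.mean([p == t for p, t in zip(pred, truth.labels)]))
            per_model.setdefault(_display(name), {})[f"acc_{part}"] = acc
    return {"table1": table, "per_model": per_model,
            "in_ad_fraction": in_ad_fraction, "validation": validation}


def regression_report(
    battery: Battery, Xact: DescriptorMatrix, yact: ActivityTable
) -> dict:
    """External validation statistics of M1–M4 and their consensus on the
    held-out active compounds."""
    from . import metrics as mx

    val_ids = battery.split_regression.validation_ids
    Xval = Xact.select_compounds(val_ids)
    y_val = yact.select_compounds(val_ids).pki
    y_tr = yact.select_compounds(battery.split_regression.train_ids).pki

    preds, levs, flags = {}, {}, {}
    out = {}
    for name, model in battery.regression_models.items():
        sub = Xval.select_descriptors(battery.regression_masks[name])
        pr = _cpann.predict_cpann(model, sub)
        lm = battery.regression_leverage[name]
        preds[name] = pr["pKi"].to_numpy()
        levs[name] = lm.leverages(Xval)
        flags[name] = pr["ad_flag"].to_numpy()
        rep = mx.regression_metrics(y_val, preds[name], y_tr)
        out[name] = {"R2": rep.r2, "RMSE": rep.rmse, "Q2_F3": rep.q2_f3,
                     "CCC": rep.ccc, "rm2": rep.rm2}

    idx = pd.Index(val_ids, name="compound_id")
    combo = cns.consensus_regression_battery(
        pd.DataFrame(preds, index=idx),
        pd.DataFrame(levs, index=idx),
        pd.DataFrame(flags, index=idx),
    )
    have = ~combo["pKi_weighted"].isna()
    if have.any():
        rep = mx.regression_metrics(
            np.asarray(y_val)[have.to_numpy()],
            combo.loc[have, "pKi_weighted"].to_numpy(),
            y_tr,
        )
        out["consensus"] = {"R2": rep.r2, "RMSE": rep.rmse, "Q2_F3": rep.q2_f3,
                            "CCC": rep.ccc, "rm2": rep.rm2,
                            "coverage": float(have.mean())}
    # model-diversity: pairwise Hamming distances between descriptor masks
    pool = battery.descriptor_pool
    bitmask = {
        name: [n in set(names) for n in pool]
        for name, names in battery.regression_masks.items()
    }
    names = list(bitmask)
    out["hamming"] = {
        f"{a}-{b}": cns.hamming_model_distance(bitmask[a], bitmask[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    return out


def regression_consensus_predictions(battery: Battery, X: DescriptorMatrix) -> pd.DataFrame:
    """Inverse-leverage consensus pKi of the regression battery for any
    compounds (ungated by the classification calls)."""
    idx = pd.Index(X.ids, name="compound_id")
    preds, levs, flags = {}, {}, {}
    for name, model in battery.regression_models.items():
        sub = X.select_descriptors(battery.regression_masks[name])
        pr = _cpann.predict_cpann(model, sub)
        preds[name] = pr["pKi"].to_numpy()
        levs[name] = battery.regression_leverage[name].leverages(X)
        flags[name] = pr["ad_flag"].to_numpy()
    return cns.consensus_regression_battery(
        pd.DataFrame(preds, index=idx),
        pd.DataFrame(levs, index=idx),
        pd.DataFrame(flags, index=idx),
    )


def run_screening(battery: Battery, X_new: DescriptorMatrix) -> tuple[pd.DataFrame, dict]:
    """Screen untested compounds with a trained battery.

    Returns the per-compound profile table (per-model call + AD flag,
    consensus calls, consensus pKi for compounds called active by at least
    one model) and a summary dict of per-model/per-consensus active counts
    and in-domain fractions.
    """
    missing = [
        n
        for names in list(battery.classification_masks.values())
        + list(battery.regression_masks.values())
        for n in names
        if n not in set(X_new.names)
    ]
    if missing:
        raise ValueError(f"screening set lacks descriptors: {sorted(set(missing))}")

    frames = _classification_labels(battery, X_new)
    n = X_new.n_compounds
    prof = pd.DataFrame(index=pd.Index(X_new.ids, name="compound_id"))
    for name, fr in frames.items():
        prof[f"{_display(name)}_label"] = list(fr["label"])
        prof[f"{_display(name)}_in_ad"] = list(fr["ad_flag"])

    votes = {
        name: [
            lab if ok else None
            for lab, ok in zip(frames[name]["label"], frames[name]["ad_flag"])
        ]
        for name in frames
    }
    triples = [[votes["nnc"][i], votes["nnd"][i], votes["qd"][i]] for i in range(n)]
    prof["consensus_A"] = [cns.consensus_classify(t, "strict").combined_label for t in triples]
    prof["consensus_A+B"] = [cns.consensus_classify(t, "A+B").combined_label for t in triples]
    for label, (a, b) in PAIR_MODES.items():
        prof[f"consensus_{label}"] = [
            cns.consensus_classify([votes[a][i], votes[b][i]], "pairwise").combined_label
            for i in range(n)
        ]

    # pKi estimate for anything called active by at least one single model
    any_active = np.zeros(n, dtype=bool)
    for name in frames:
        any_active |= prof[f"{_display(name)}_label"].to_numpy() == ACTIVE
    combo = regression_consensus_predictions(battery, X_new)
    pki = combo["pKi_weighted"].copy()
    pki[~any_active] = np.nan
    prof["pKi_consensus"] = pki

    summary = {
        "n_compounds": n,
        "actives_per_model": {
            _display(name): int((prof[f"{_display(name)}_label"] == ACTIVE).sum())
            for name in frames
        },
        "in_ad_per_model": {
            _display(name): int(prof[f"{_display(name)}_in_ad"].sum()) for name in frames
        },
        "actives_per_consensus": {
            c: int((prof[f"consensus_{c}"] == ACTIVE).sum())
            for c in ["A", "A+B", *PAIR_MODES]
        },
        "predicted_per_consensus": {
            c: int((prof[f"consensus_{c}"] != cns.NO_PREDICTION).sum())
            for c in ["A", "A+B", *PAIR_MODES]
        },
        "n_with_pki_estimate": int(prof["pKi_consensus"].notna().sum()),
    }
    return prof, summary


def _display(name: str) -> str:
    return {"nnc": "NN-C", "nnd": "NN-D", "qd": "Q-D"}.get(name, name)
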