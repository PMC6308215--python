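"""End-to-end orchestration: curate -> transform -> split -> model -> AD -> categories.

One :class:`RunConfig` drives a full run on either a user CSV (columns id,
smiles, fu[, pka_acid, pka_base]) or a synthetic dataset.  Outputs are a
predictions CSV (observed, predicted, in-AD flag per requested method), a
model report JSON with internal (cross-validated) and external metrics, a
category enrichment TSV, and a manifest recording every seed, threshold and
output-file hash so a run is fully self-describing and reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import applicability, category_analysis, coral, descriptor_model, synthetic
from .curation import CompoundRecord, curate_records, parse_fu
from .endpoints import transform_endpoint
from .splitting import activity_binned_split, coral_subsplit

__all__ = ["RunConfig", "run_pipeline", "load_compound_csv"]


@dataclass
class RunConfig:
    output_dir: str = "ppbqsar_run"
    input_csv: str | None = None  # None -> synthetic data
    synthetic_n: int = 300
    transform: str = "sqrt_fu"
    subset: str = "all"  # all | acid | base | neutral | zwitterion
    model: str = "coral"  # coral | descriptor_rf
    use_ionized: bool = False
    split_ratio: float = 0.8
    n_bins: int = 5
    ad_methods: tuple = ("leverage", "pca_sd", "knn_dist", "acf", "fingerprint")
    seed: int = 0
    coral_T: int = 1
    coral_N: int = 20
    rf_trees: int = 200
    vsurf: bool = False
    vsurf_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ad_methods" in raw:
            raw["ad_methods"] = tuple(raw["ad_methods"])
        return cls(**raw)

    def validate(self) -> None:
        if self.model not in ("coral", "descriptor_rf"):
            raise ValueError(f"unknown model kind {self.model!r}")
        if self.subset not in ("all", "acid", "base", "neutral", "zwitterion"):
            raise ValueError(f"unknown subset {self.subset!r}")
        for m in self.ad_methods:
            if m not in applicability.AD_METHODS:
                raise ValueError(f"unknown AD method {m!r}")


def load_compound_csv(path) -> list[CompoundRecord]:
    """Read the standard compound CSV into raw records."""
    df = pd.read_csv(path, dtype={"id": str})
    records = []
    for _, row in df.iterrows():
        fu, reason = parse_fu(row.get("fu"))
        rec = CompoundRecord(id=str(row["id"]), smiles_raw=str(row["smiles"]), fu=fu)
        if reason is not None:
            rec.reject(reason)
        for col, attr in (("pka_acid", "pka_acid"), ("pka_base", "pka_base")):
            if col in df.columns and isinstance(row[col], str) and row[col].strip():
                setattr(rec, attr, [float(v) for v in row[col].split("|")])
        records.append(rec)
    return records


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _seeds(master: int) -> dict:
    ss = np.random.SeedSequence(master)
    names = ("synthetic", "split", "subsplit", "model", "cv", "ad")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run; returns the manifest dictionary."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seeds(config.seed)

    # --- input
    if config.input_csv is None:
        syn_cfg = synthetic.SyntheticConfig(
            n_compounds=config.synthetic_n, seed=seeds["synthetic"]
        )
        records = synthetic.generate_dataset(syn_cfg)
    else:
        records = load_compound_csv(config.input_csv)

    # --- curation
    records = curate_records(records)
    rejected = [(r.id, r.reject_reason) for r in records if r.rejected]
    kept = [r for r in records if not r.rejected]
    if not kept:
        raise RuntimeError("curation rejected every record")
    audit_path = out / "rejected.tsv"
    with open(audit_path, "w") as fh:
        fh.write("id\treason\n")
        for rid, reason in rejected:
            fh.write(f"{rid}\t{reason}\n")

    if config.subset != "all":
        kept = [r for r in kept if r.ionization_class == config.subset]
        if len(kept) < 3 * config.n_bins:
            raise RuntimeError(
                f"subset {config.subset!r} leaves too few compounds ({len(kept)})"
            )
    for rec in kept:
        if not rec.categories:
            rec.categories = category_analysis.assign_categories(rec.smiles_std)

    # --- endpoint + split
    endpoint = transform_endpoint(
        [r.fu for r in kept], [r.id for r in kept], config.transform
    )
    split = activity_binned_split(
        endpoint, ratio=config.split_ratio, n_bins=config.n_bins, seed=seeds["split"]
    )
    by_id = {r.id: r for r in kept}
    y = dict(zip(endpoint.source_ids, endpoint.values))
    ts_ids = [i for i in endpoint.source_ids if split.role[i] == "TS"]
    evs_ids = [i for i in endpoint.source_ids if split.role[i] == "EVS"]

    report: dict = {"model": config.model, "transform": config.transform, "seeds": seeds}

    # --- model
    if config.model == "coral":
        subrole = coral_subsplit(ts_ids, seed=seeds["subsplit"])
        smiles_ts = [by_id[i].smiles_std for i in ts_ids]
        roles = [subrole[i] for i in ts_ids]
        model = coral.CoralRegressor(
            threshold_T=config.coral_T,
            epochs_N=config.coral_N,
            random_state=seeds["model"],
        )
        model.fit(smiles_ts, [y[i] for i in ts_ids], roles=roles)
        pred_ts = model.predict(smiles_ts)
        pred_evs = model.predict([by_id[i].smiles_std for i in evs_ids])
        # internal statistic aggregates the three sub-sets, i.e. the whole TS
        q2, _ = None, None
        r2_int, rmse_int = descriptor_model.regression_metrics(
            [y[i] for i in ts_ids], pred_ts
        )
        report["internal"] = {"r2": r2_int, "rmse": rmse_int}
        report["coral"] = {
            "T": config.coral_T,
            "N": config.coral_N,
            "n_active_attributes": len(model.active_attributes_),
            "best_tf": model.best_tf_,
        }
        coral_in_ad = model.in_domain([by_id[i].smiles_std for i in evs_ids])
        X_desc = None
    else:
        X = descriptor_model.compute_descriptors(kept, use_ionized=config.use_ionized)
        X = descriptor_model.prefilter(X)
        ts_ids = [i for i in ts_ids if i in X.data.index]
        evs_ids = [i for i in evs_ids if i in X.data.index]
        X_ts, X_evs = X.data.loc[ts_ids], X.data.loc[evs_ids]
        y_ts = np.array([y[i] for i in ts_ids])
        cols = list(X_ts.columns)
        if config.vsurf:
            cols = descriptor_model.vsurf_select(
                X_ts, y_ts, params=config.vsurf_params, seed=seeds["model"]
            )
            X_ts, X_evs = X_ts[cols], X_evs[cols]
        model = descriptor_model.fit_rf(
            X_ts, y_ts, seed=seeds["model"], n_estimators=config.rf_trees
        )
        q2, _ = descriptor_model.cross_validate_q2(X_ts, y_ts, seed=seeds["cv"])
        pred_ts = model.predict(X_ts.to_numpy(dtype=float))
        pred_evs = model.predict(X_evs.to_numpy(dtype=float))
        report["internal"] = {"q2": q2}
        report["selected_descriptors"] = cols
        coral_in_ad = None
        X_desc = X

    # --- external metrics
    y_evs = np.array([y[i] for i in evs_ids])
    if len(evs_ids) >= 2:
        r2_ext, rmse_ext = descriptor_model.regression_metrics(y_evs, pred_evs)
        report["external"] = {"r2": r2_ext, "rmse": rmse_ext, "n": len(evs_ids)}

    # --- applicability domains on the EVS
    if X_desc is None and any(
        m not in applicability.STRUCTURE_METHODS for m in config.ad_methods
    ):
        X_desc = descriptor_model.prefilter(
            descriptor_model.compute_descriptors(kept, use_ionized=config.use_ionized)
        )
    ad_flags: dict[str, dict] = {}
    ad_params: dict[str, dict] = {}
    for method in config.ad_methods:
        if method in applicability.STRUCTURE_METHODS:
            fit_in = [by_id[i].smiles_std for i in ts_ids]
            test_in = [by_id[i].smiles_std for i in evs_ids]
        else:
            fit_in = X_desc.data.loc[[i for i in ts_ids if i in X_desc.data.index]]
            test_in = X_desc.data.loc[[i for i in evs_ids if i in X_desc.data.index]]
        ad = applicability.fit_ad(method, fit_in, seed=seeds["ad"])
        verdict = applicability.apply_ad(ad, test_in, ids=evs_ids)
        ad_flags[method] = verdict.in_ad
        ad_params[method] = verdict.threshold_params
        report.setdefault("ad", {})[method] = {
            "coverage": verdict.coverage,
            "params": verdict.threshold_params,
        }
    if coral_in_ad is not None:
        ad_flags["coral_ad"] = dict(zip(evs_ids, (bool(b) for b in coral_in_ad)))
        report.setdefault("ad", {})["coral_ad"] = {
            "coverage": float(np.mean(coral_in_ad)) if len(evs_ids) else 0.0
        }

    # AD-filtered external metrics
    for method, flags in ad_flags.items():
        in_ids = [i for i in evs_ids if flags.get(i)]
        if len(in_ids) >= 3:
            idx = [evs_ids.index(i) for i in in_ids]
            r2_ad, rmse_ad = descriptor_model.regression_metrics(
                y_evs[idx], np.asarray(pred_evs)[idx]
            )
            report["ad"][method].update({"r2_in_ad": r2_ad, "rmse_in_ad": rmse_ad})

    # --- predictions CSV
    pred_rows = []
    pred_map = dict(zip(ts_ids, pred_ts)) | dict(zip(evs_ids, pred_evs))
    for i in ts_ids + evs_ids:
        row = {
            "id": i,
            "role": split.role[i],
            "observed": f"{y[i]:.10g}",
            "predicted": f"{pred_map[i]:.10g}",
        }
        for method, flags in ad_flags.items():
            row[f"in_ad_{method}"] = flags.get(i, "")
        pred_rows.append(row)
    pred_path = out / "predictions.csv"
    pd.DataFrame(pred_rows).to_csv(pred_path, index=False)

    # --- outlier / category analysis on the TS
    abs_err = np.abs(np.array([y[i] for i in ts_ids]) - np.asarray(pred_ts))
    flags = category_analysis.flag_outliers(abs_err)
    stats = category_analysis.category_report([by_id[i] for i in ts_ids], flags)
    cat_path = out / "categories.tsv"
    with open(cat_path, "w") as fh:
        fh.write("category\tdirection\ttp\tfp\tpositives\tnegatives\tp_value\tlr\tsignificant\n")
        for s in stats:
            fh.write(
                f"{s.category}\t{s.direction}\t{s.tp}\t{s.fp}\t{s.positives}\t"
                f"{s.negatives}\t{s.p_value:.6g}\t{s.lr:.6g}\t{s.significant}\n"
            )

    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        "seeds": seeds,
        "n_input": len(records),
        "n_kept": len(kept),
        "n_rejected": len(rejected),
        "n_ts": len(ts_ids),
        "n_evs": len(evs_ids),
        "ad_params": ad_params,
        "files": {
            p.name: _sha256(p) for p in (pred_path, report_path, cat_path, audit_path)
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
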