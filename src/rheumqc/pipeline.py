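"""End-to-end workflows tying the analysis stages together.

Two workflows mirror the two study designs:

* the *commercial* workflow (28-sample scale): fingerprint similarity and
  RSI grouping → two-group t tests on compounds and class totals → DL curve
  fitting and replicate averaging → OPLS-DA on the chemical and DL blocks →
  thresholded Spearman correlation network between compounds/class totals
  and DL properties;
* the *wild* workflow (118-sample scale): PCA on the chemical and DL blocks
  → Ward clustering of the DL properties into two groups (the cluster with
  the higher DL values is named "1") → group comparison of DL properties
  and chemical class totals.

Each run writes its stage outputs as CSV/TSV plus a JSON summary and a
manifest (inputs, config hash, package version, seed) sufficient to
re-execute the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .bioassay import diarrhea_tests, group_summary, posthoc, read_defecation_csv
from .chemometrics import (
    FeatureMatrix,
    correlation_network,
    edges_to_frame,
    oplsda,
    pca,
    ttest_two_group,
    ward_hclust,
)
from .dl_kinetics import (
    DLCurve,
    average_replicates,
    fit_hyperbolic,
    fits_to_frame,
    properties_to_frame,
)
from .fingerprint import (
    DEFAULT_HIGH_THRESHOLD,
    DEFAULT_LOW_THRESHOLD,
    build_common_peak_matrix,
    read_peak_table_csv,
    relative_quantities,
    similarity_matrix,
)
from .synthetic_data import GLYCOSIDES, SyntheticCohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_commercial_workflow", "run_wild_workflow"]


@dataclass
class RunConfig:
    """Options shared by the workflows; all thresholds surfaced, none hidden."""

    outdir: str = "rheumqc_out"
    seed: int = 0
    fit_objective: str = "poisson"
    similarity_method: str = "cosine"
    reference_peak: int = 13
    rsi_high: float = DEFAULT_HIGH_THRESHOLD
    rsi_low: float = DEFAULT_LOW_THRESHOLD
    cv_folds: int = 7
    n_orthogonal: int = 1
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _write_manifest(config: RunConfig, outdir: str, inputs: Mapping[str, str]) -> None:
    manifest = {
        "package": "rheumqc",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "inputs": dict(inputs),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def _fit_dl_properties(curves: list[DLCurve], config: RunConfig):
    fits = [fit_hyperbolic(c, objective=config.fit_objective) for c in curves]
    by_sample: dict[str, list] = {}
    for f in fits:
        by_sample.setdefault(f.sample_id, []).append(f)
    props = [average_replicates(fs) for fs in by_sample.values()]
    return fits, props


def _ttest_table(df: pd.DataFrame, groups: pd.Series, alpha: float) -> pd.DataFrame:
    rows = []
    mask_a = groups == "A"
    mask_b = groups == "B"
    for col in df.columns:
        a, b = df.loc[mask_a, col], df.loc[mask_b, col]
        t, dof, p = ttest_two_group(a, b)
        rows.append(
            {
                "feature": col,
                "mean_A": a.mean(),
                "mean_B": b.mean(),
                "t": t,
                "df": dof,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def run_commercial_workflow(cohort: SyntheticCohort, config: RunConfig) -> dict:
    """Fingerprint → grouping → t tests → DL fitting → OPLS-DA → network.

    Returns the JSON-ready summary dict; all stage outputs are written under
    ``config.outdir``.
    """
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    summary: dict = {"workflow": "commercial", "seed": config.seed}

    # -- stage: fingerprint similarity and RSI grouping
    logger.info("stage: fingerprint")
    tables = _peak_tables_from_frame(cohort.peak_tables)
    matrix = build_common_peak_matrix(tables, reference_peak_id=config.reference_peak)
    vectors = relative_quantities(matrix)
    sim = similarity_matrix(
        vectors,
        method=config.similarity_method,
        high_threshold=config.rsi_high,
        low_threshold=config.rsi_low,
    )
    pw, rsi_table = sim.to_frames()
    pw.round(3).to_csv(os.path.join(outdir, "similarity_matrix.csv"))
    rsi_table.assign(rsi=rsi_table["rsi"].round(3)).to_csv(
        os.path.join(outdir, "rsi_groups.csv"), index=False
    )
    groups = pd.Series(
        rsi_table["group"].to_numpy(), index=rsi_table["sample_id"], name="group"
    )
    summary["rsi_groups"] = groups.to_dict()

    # unassigned samples are excluded from two-group statistics
    assigned = groups[groups.isin(["A", "B"])]
    if len(assigned) < len(groups):
        logger.warning(
            "%d sample(s) unassigned by RSI; excluded from group statistics",
            len(groups) - len(assigned),
        )

    # -- stage: two-group t tests on compounds and class totals
    logger.info("stage: group t tests")
    comp = cohort.compounds.loc[assigned.index]
    totals = cohort.class_totals.loc[assigned.index]
    two_groups = min((assigned == "A").sum(), (assigned == "B").sum()) >= 2
    if two_groups:
        ttests = pd.concat(
            [
                _ttest_table(comp, assigned, config.alpha),
                _ttest_table(totals, assigned, config.alpha),
            ],
            ignore_index=True,
        )
        summary["significant_compounds"] = ttests.loc[
            ttests["significant"], "feature"
        ].tolist()
    else:
        logger.warning(
            "RSI grouping produced fewer than two samples in one group; "
            "two-group statistics skipped"
        )
        ttests = pd.DataFrame(
            columns=["feature", "mean_A", "mean_B", "t", "df", "p", "significant"]
        )
        summary["significant_compounds"] = []
    ttests.to_csv(os.path.join(outdir, "group_ttests.csv"), index=False)

    # -- stage: DL fitting and replicate averaging
    logger.info("stage: DL fitting (%d curves)", len(cohort.dl_curves))
    fits, props = _fit_dl_properties(cohort.dl_curves, config)
    fits_to_frame(fits).to_csv(os.path.join(outdir, "dl_fits.csv"), index=False)
    props_df = properties_to_frame(props).set_index("sample_id")
    props_df.to_csv(os.path.join(outdir, "dl_properties.csv"))

    # -- stage: OPLS-DA on chemical and DL blocks
    logger.info("stage: OPLS-DA")
    if two_groups:
        # log-transform concentrations before autoscaling: assay data are
        # lognormal and squared-error CV statistics are outlier-dominated otherwise
        chem_fm = FeatureMatrix.from_frame(np.log(comp), labels=assigned)
        chem_model = oplsda(
            chem_fm,
            n_orthogonal=config.n_orthogonal,
            cv_folds=config.cv_folds,
            seed=config.seed,
        )
        dl_block = props_df.loc[assigned.index, ["I0", "Tau", "Beta", "T"]]
        dl_fm = FeatureMatrix.from_frame(dl_block, labels=assigned)
        dl_model = oplsda(
            dl_fm,
            n_orthogonal=config.n_orthogonal,
            cv_folds=config.cv_folds,
            seed=config.seed,
        )
        summary["oplsda"] = {
            "chemical": {"R2": chem_model.R2, "Q2": chem_model.Q2},
            "dl": {"R2": dl_model.R2, "Q2": dl_model.Q2},
        }
    else:
        logger.warning("OPLS-DA skipped: RSI grouping is degenerate")
        summary["oplsda"] = None

    # -- stage: compound-DL correlation network
    logger.info("stage: correlation network")
    features = pd.concat([cohort.compounds, cohort.class_totals], axis=1)
    net_fm = FeatureMatrix.from_frame(features)
    dl_all = props_df.loc[list(net_fm.sample_ids), ["I0", "Tau", "Beta", "T"]]
    edges = correlation_network(net_fm, dl_all)
    edge_df = edges_to_frame(edges)
    edge_df.to_csv(os.path.join(outdir, "correlation_edges.tsv"), sep="\t", index=False)
    flagged = edge_df[edge_df["linear_relationship"]]
    summary["network"] = {
        "n_edges_flagged": int(len(flagged)),
        "glycoside_edges": flagged[flagged["compound"] == "glycoside_total"][
            ["dl_property", "rho", "sign", "strength"]
        ].to_dict("records"),
    }

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    _write_manifest(config, outdir, {"cohort_seed": str(cohort.spec.seed)})
    return summary


def run_wild_workflow(cohort: SyntheticCohort, config: RunConfig) -> dict:
    """PCA → Ward clustering of DL properties → group comparisons.

    DL properties come from the cohort's truth table when curves were not
    simulated, otherwise from fitting the curves.  The cluster with the
    higher mean DL values is named group "1".
    """
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    summary: dict = {"workflow": "wild", "seed": config.seed}

    if cohort.dl_curves:
        _, props = _fit_dl_properties(cohort.dl_curves, config)
        dl = properties_to_frame(props).set_index("sample_id")[["I0", "Tau", "Beta", "T"]]
        dl = dl.loc[cohort.compounds.index]
    else:
        dl = cohort.dl_truth[["I0", "Tau", "Beta", "T"]]

    logger.info("stage: PCA")
    chem_model = pca(FeatureMatrix.from_frame(cohort.compounds))
    dl_model = pca(FeatureMatrix.from_frame(dl))
    for name, model in (("chemical", chem_model), ("dl", dl_model)):
        pd.DataFrame(
            model.scores,
            index=list(model.sample_ids),
            columns=[f"PC{i+1}" for i in range(model.scores.shape[1])],
        ).to_csv(os.path.join(outdir, f"pca_scores_{name}.csv"))
    summary["pca_explained_variance"] = {
        "chemical": (chem_model.explained_variance / chem_model.explained_variance.sum()).tolist(),
        "dl": (dl_model.explained_variance / dl_model.explained_variance.sum()).tolist(),
    }

    logger.info("stage: Ward clustering of DL properties")
    if np.allclose(dl.to_numpy().std(axis=0), 0):
        logger.warning("degenerate DL block (no variation); clustering is arbitrary")
    # autoscale before clustering so all four properties carry equal weight
    scaled = (dl - dl.mean()) / dl.std(ddof=1)
    labels, Z = ward_hclust(FeatureMatrix.from_frame(scaled), k=2)
    labels = pd.Series(labels, index=dl.index, name="cluster")
    # name the high-DL cluster "1" (mean of autoscaled properties)
    means = scaled.groupby(labels).mean().mean(axis=1)
    high = means.idxmax()
    named = labels.map(lambda c: "1" if c == high else "2")
    named.rename("dl_group").to_csv(os.path.join(outdir, "dl_clusters.csv"))

    logger.info("stage: group comparisons")
    groups = named.map({"1": "A", "2": "B"})  # reuse two-group t-test helper
    summary["cluster_sizes"] = named.value_counts().to_dict()
    if min((groups == "A").sum(), (groups == "B").sum()) >= 2:
        dl_tests = _ttest_table(dl, groups, config.alpha).rename(
            columns={"mean_A": "mean_group1", "mean_B": "mean_group2"}
        )
        totals = cohort.class_totals.loc[dl.index]
        total_tests = _ttest_table(totals, groups, config.alpha).rename(
            columns={"mean_A": "mean_group1", "mean_B": "mean_group2"}
        )
        comparisons = pd.concat([dl_tests, total_tests], ignore_index=True)
        comparisons.to_csv(os.path.join(outdir, "wild_group_tests.csv"), index=False)
        summary["dl_property_comparison"] = dl_tests.to_dict("records")
        summary["class_total_comparison"] = total_tests.to_dict("records")
    else:
        logger.warning("degenerate clustering (a cluster has < 2 samples); comparisons skipped")
        summary["dl_property_comparison"] = []
        summary["class_total_comparison"] = []

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    _write_manifest(config, outdir, {"cohort_seed": str(cohort.spec.seed)})
    return summary


def run_bioassay_analysis(defecation: pd.DataFrame, config: RunConfig) -> dict:
    """Group summaries, ANOVA + post hoc and diarrhea tests on per-mouse records."""
    from .bioassay import DefecationRecord, anova_oneway

    records = [
        DefecationRecord(
            mouse_id=str(r.mouse_id),
            group=str(r.group),
            dose=float(r.dose_g_per_kg),
            incubation_min=None if pd.isna(r.incubation_min) else float(r.incubation_min),
            n_charcoal_feces=int(r.n_feces),
            feces_weight_mg=float(r.feces_mg),
            loose_stools=bool(r.loose),
        )
        for r in defecation.itertuples()
    ]
    summary_df = group_summary(records)
    group_names = summary_df["group"].tolist()
    by_group = {
        g: defecation.loc[defecation["group"] == g] for g in group_names
    }
    endpoints = {}
    for col in ("n_feces", "feces_mg"):
        groups_vals = [by_group[g][col].to_numpy(dtype=float) for g in group_names]
        F, dfb, dfw, p = anova_oneway(groups_vals)
        ph = posthoc(groups_vals, group_names, method="auto", alpha=config.alpha)
        endpoints[col] = {
            "anova": {"F": F, "df": [dfb, dfw], "p": p},
            "posthoc_method": ph.attrs["method"],
            "n_significant_pairs": int(ph["significant"].sum()),
        }
    counts = pd.DataFrame(
        {
            "loose": [int(by_group[g]["loose"].sum()) for g in group_names],
            "not_loose": [
                int((~by_group[g]["loose"].astype(bool)).sum()) for g in group_names
            ],
        },
        index=group_names,
    )
    overall_p, fisher = diarrhea_tests(counts)
    return {
        "group_summary": summary_df.to_dict("records"),
        "endpoints": endpoints,
        "diarrhea": {
            "chi_square_p": overall_p,
            "pairwise_fisher": fisher.to_dict("records"),
        },
    }


def _peak_tables_from_frame(df: pd.DataFrame):
    """Long peak frame -> list of PeakTable (same contract as the CSV reader)."""
    from .fingerprint import PeakTable

    return [
        PeakTable(
            sample_id=str(sid),
            peaks=tuple(
                (int(r.peak_id), float(r.rt_min), float(r.area)) for r in grp.itertuples()
            ),
        )
        for sid, grp in df.groupby("sample_id", sort=True)
    ]
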