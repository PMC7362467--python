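"""Synthetic cohorts with the statistical structure the pipeline assumes.

No public rhubarb dataset accompanies the analysis, so every pipeline stage
is exercised on generated cohorts that plant the qualitative structure the
method is meant to detect:

* two chemical sub-groups ("A" majority, "B" minority) that differ in the
  glycoside-containing compounds (anthraquinone glucosides + sennoside A),
  with free anthraquinones and polyphenols shared between groups;
* four delayed-luminescence properties negatively linked to the log
  glycoside total, realised both as a truth table and as Poisson-sampled
  triplicate decay curves;
* a 28-common-peak HPLC layout in which the 15 identified compounds map to
  distinct peaks and the reference peak (No. 13) is a stable baseline peak;
* a seven-group mouse bioassay (control + two samples × three doses) with
  dose- and sample-dependent diarrhea probability and cathartic endpoints.

Concentrations are lognormal (strictly positive and right-skewed, as
natural-product assays are).  The species factor is generated but carries
no chemical effect, matching the finding that sub-species do not separate.
A cohort is fully determined by its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dl_kinetics import DLCurve, decay_time, simulate_curve

__all__ = [
    "FREE_ANTHRAQUINONES",
    "GLYCOSIDES",
    "POLYPHENOLS",
    "COMPOUNDS",
    "CohortSpec",
    "SyntheticCohort",
    "generate_compounds",
    "generate_dl",
    "generate_peaks",
    "generate_bioassay",
    "generate_cohort",
]

FREE_ANTHRAQUINONES = (
    "aloe-emodin",
    "rhein",
    "emodin",
    "chrysophanol",
    "physcion",
)
GLYCOSIDES = (
    "aloe-emodin-8-O-glucoside",
    "rhein-8-O-glucoside",
    "emodin-1-O-glucoside",
    "emodin-8-O-glucoside",
    "chrysophanol-1-O-glucoside",
    "chrysophanol-8-O-glucoside",
    "physcion-8-O-glucoside",
    "sennoside A",
)
POLYPHENOLS = ("gallic acid", "(+)-catechin")
COMPOUNDS = FREE_ANTHRAQUINONES + GLYCOSIDES + POLYPHENOLS

CLASS_OF = {
    **{c: "free_anthraquinone" for c in FREE_ANTHRAQUINONES},
    **{c: "glycoside" for c in GLYCOSIDES},
    **{c: "polyphenol" for c in POLYPHENOLS},
}

SPECIES = (
    "Rheum officinale",
    "Rheum palmatum",
    "Rheum tanguticum",
)

N_COMMON_PEAKS = 28
REFERENCE_PEAK = 13

# 15 compounds -> distinct common peaks (reference peak 13 stays a baseline peak)
DEFAULT_PEAK_MAP: dict[str, int] = {
    "gallic acid": 1,
    "(+)-catechin": 3,
    "aloe-emodin-8-O-glucoside": 6,
    "rhein-8-O-glucoside": 8,
    "sennoside A": 9,
    "emodin-1-O-glucoside": 10,
    "emodin-8-O-glucoside": 12,
    "chrysophanol-1-O-glucoside": 14,
    "chrysophanol-8-O-glucoside": 16,
    "physcion-8-O-glucoside": 17,
    "aloe-emodin": 20,
    "rhein": 22,
    "emodin": 24,
    "chrysophanol": 26,
    "physcion": 27,
}


def _default_compound_means() -> dict[str, tuple[float, float]]:
    """Per-compound (group A mean, group B mean) in mg/g, natural scale.

    Glycoside-containing compounds are doubled in group B; the other classes
    are shared.  Values sit in the low-mg/g range typical of rhubarb assays.
    """
    means: dict[str, tuple[float, float]] = {}
    for c in FREE_ANTHRAQUINONES:
        means[c] = (3.0, 3.0)
    for c in GLYCOSIDES:
        means[c] = (2.5, 5.0)
    for c in POLYPHENOLS:
        means[c] = (2.0, 2.0)
    return means


@dataclass(frozen=True)
class CohortSpec:
    """Parameters that fully determine a synthetic cohort.

    ``dl_link`` maps each DL property to (intercept, slope, noise_sd) of the
    linear-in-log link  property = intercept - slope * log(glycoside total)
    + N(0, noise_sd), clipped positive.
    """

    n_samples: int = 28
    group_fraction_A: float = 17 / 28
    compound_means: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_compound_means
    )
    compound_cv: float = 0.25
    # the glycoside-rich minority group is heterogeneous in WHICH glucosides
    # dominate: every group-B sample additionally spikes a random subset of
    # glycoside compounds, so B fingerprints are mutually dissimilar (their
    # pairwise similarities are low) while all share an elevated class total
    n_spike_glycosides: int = 2
    spike_factor: float = 8.0
    spike_sigma: float = 0.5  # lognormal sigma of the spike multiplier
    # slopes chosen so the derived decay time T also falls with glycoside
    # content: Tau must drop faster than exp(1/Beta)-1 grows as Beta falls
    dl_link: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "I0": (9000.0, 1600.0, 150.0),
            "Tau": (0.62, 0.11, 0.012),
            "Beta": (2.6, 0.20, 0.04),
        }
    )
    peak_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_PEAK_MAP))
    peak_noise_sd: float = 0.10  # lognormal sigma on compound-peak areas
    calibration_slope: float = 1.0e4  # detector units per (mg/g)
    baseline_area: float = 1.2e5  # baseline common peaks incl. reference
    rt_jitter_sd: float = 0.05  # minutes
    n_replicates: int = 3
    dl_background: float = 0.5  # dark counts per 0.05-s bin (~10 counts/s)
    # bioassay: logit(p_loose) = intercept + slope * dose for each sample
    diarrhea_logit: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"S10": (-4.4, 0.8), "S22": (-4.4, 1.6)}
    )
    control_p_loose: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.group_fraction_A <= 1:
            raise ValueError("group_fraction_A must lie in [0, 1]")
        if self.compound_cv < 0 or self.peak_noise_sd < 0:
            raise ValueError("variances must be non-negative")
        missing = set(COMPOUNDS) - set(self.peak_map)
        if missing:
            raise ValueError(f"peak_map does not cover compounds: {sorted(missing)}")
        for name, (a, b) in self.compound_means.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"non-positive mean for compound {name!r}")

    @classmethod
    def commercial_default(cls, seed: int = 0) -> "CohortSpec":
        """28-sample commercial-cohort design (17 group-A, 11 group-B)."""
        return cls(seed=seed)

    @classmethod
    def wild_default(cls, seed: int = 0) -> "CohortSpec":
        """118-sample wild-cohort design (two latent groups, balanced)."""
        return cls(n_samples=118, group_fraction_A=0.5, seed=seed)

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


@dataclass
class SyntheticCohort:
    """All generated artifacts of one cohort."""

    spec: CohortSpec
    compounds: pd.DataFrame          # samples x 15 concentrations (mg/g)
    class_totals: pd.DataFrame       # samples x 3 class sums
    group_labels: pd.Series          # true group per sample ("A"/"B")
    species: pd.Series
    dl_truth: pd.DataFrame           # samples x (I0, Tau, Beta, T)
    dl_curves: list[DLCurve]
    peak_tables: pd.DataFrame        # long: sample_id, peak_id, rt_min, area
    defecation: pd.DataFrame
    propulsion: pd.DataFrame


def _lognormal_from_mean(mean: float, cv: float, size, rng) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def generate_compounds(spec: CohortSpec, rng: np.random.Generator):
    """Compound concentrations, class totals and true group labels.

    Returns ``(compounds, class_totals, groups, species)``; the class totals
    are exact sums of their member compounds.
    """
    n = spec.n_samples
    n_a = int(round(spec.group_fraction_A * n))
    groups = pd.Series(
        ["A"] * n_a + ["B"] * (n - n_a),
        index=[f"S{i+1}" for i in range(n)],
        name="group",
    )
    # interleave so group doesn't align with sample numbering
    order = rng.permutation(n)
    groups = pd.Series(groups.to_numpy()[order], index=groups.index, name="group")
    species = pd.Series(
        [SPECIES[i % len(SPECIES)] for i in range(n)], index=groups.index, name="species"
    )
    data = {}
    is_b = groups.to_numpy() == "B"
    for name in COMPOUNDS:
        mean_a, mean_b = spec.compound_means[name]
        means = np.where(is_b, mean_b, mean_a)
        data[name] = np.array(
            [_lognormal_from_mean(m, spec.compound_cv, None, rng) for m in means]
        )
    compounds = pd.DataFrame(data, index=groups.index)
    # per-sample glycoside spikes in group B: a random subset of glucosides
    # dominates each glycoside-rich sample
    if spec.n_spike_glycosides > 0:
        gly_cols = list(GLYCOSIDES)
        for idx in np.flatnonzero(is_b):
            chosen = rng.choice(
                len(gly_cols), size=min(spec.n_spike_glycosides, len(gly_cols)), replace=False
            )
            for j in chosen:
                factor = spec.spike_factor * rng.lognormal(0.0, spec.spike_sigma)
                compounds.iloc[idx, compounds.columns.get_loc(gly_cols[j])] *= factor
    class_totals = pd.DataFrame(
        {
            "free_anthraquinone_total": compounds[list(FREE_ANTHRAQUINONES)].sum(axis=1),
            "glycoside_total": compounds[list(GLYCOSIDES)].sum(axis=1),
            "polyphenol_total": compounds[list(POLYPHENOLS)].sum(axis=1),
        }
    )
    return compounds, class_totals, groups, species


def generate_dl(
    spec: CohortSpec,
    compounds: pd.DataFrame,
    rng: np.random.Generator,
    simulate_curves: bool = True,
):
    """DL truth parameters linked to glycoside content, plus triplicate curves.

    Each of I0/Tau/Beta follows ``intercept - slope*log(glycoside total)``
    with Gaussian noise, clipped to stay positive; T derives from (Beta, Tau)
    so all four properties inherit the planted negative link.
    """
    gly = compounds[list(GLYCOSIDES)].sum(axis=1)
    log_g = np.log(gly.to_numpy())
    truth = {}
    floors = {"I0": 50.0, "Tau": 0.02, "Beta": 0.2}
    for prop, (icpt, slope, sd) in spec.dl_link.items():
        vals = icpt - slope * log_g + rng.normal(0.0, sd, len(log_g))
        floor = floors.get(prop, 1e-6)
        if np.any(vals <= floor):
            import warnings

            warnings.warn(f"clipping non-positive generated {prop} values", stacklevel=2)
        truth[prop] = np.maximum(vals, floor)
    dl_truth = pd.DataFrame(truth, index=compounds.index)
    dl_truth["T"] = [
        decay_time(b, t) for b, t in zip(dl_truth["Beta"], dl_truth["Tau"])
    ]
    curves: list[DLCurve] = []
    if simulate_curves:
        for sid, row in dl_truth.iterrows():
            for rep in range(1, spec.n_replicates + 1):
                curves.append(
                    simulate_curve(
                        I0=row["I0"],
                        Tau=row["Tau"],
                        Beta=row["Beta"],
                        rng=rng,
                        sample_id=str(sid),
                        replicate_index=rep,
                        background=spec.dl_background,
                    )
                )
    return dl_truth, curves


def generate_peaks(
    spec: CohortSpec, compounds: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Long-format common-peak tables (sample_id, peak_id, rt_min, area).

    Compound peaks scale linearly with concentration under a shared
    calibration slope with lognormal noise; the remaining common peaks —
    including the reference peak — come from a shared baseline template.
    Retention times follow a fixed template with small jitter.
    """
    peak_ids = np.arange(1, N_COMMON_PEAKS + 1)
    # fixed retention-time template: 28 peaks spread over a 100-min gradient
    rt_template = 5.0 + 95.0 * (peak_ids - 1) / (N_COMMON_PEAKS - 1)
    compound_of_peak = {pid: c for c, pid in spec.peak_map.items()}
    rows = []
    for sid in compounds.index:
        rt = rt_template + rng.normal(0.0, spec.rt_jitter_sd, N_COMMON_PEAKS)
        rt = np.sort(rt)  # jitter is small but never reorder peaks
        for pid, rt_min in zip(peak_ids, rt):
            if pid in compound_of_peak:
                conc = compounds.at[sid, compound_of_peak[pid]]
                area = spec.calibration_slope * conc
            else:
                area = spec.baseline_area * (1.2 if pid == REFERENCE_PEAK else 1.0)
            if spec.peak_noise_sd > 0:
                area *= rng.lognormal(0.0, spec.peak_noise_sd)
            rows.append(
                {"sample_id": sid, "peak_id": int(pid), "rt_min": rt_min, "area": area}
            )
    return pd.DataFrame(rows)


BIOASSAY_DESIGN = (
    # (group, sample, dose g/kg, n defecation, n propulsion)
    ("Control", None, 0.0, 8, 8),
    ("S10-Low", "S10", 1.0, 8, 8),
    ("S10-Medium", "S10", 2.5, 8, 9),
    ("S10-High", "S10", 5.0, 9, 9),
    ("S22-Low", "S22", 1.0, 8, 8),
    ("S22-Medium", "S22", 2.5, 8, 9),
    ("S22-High", "S22", 5.0, 9, 9),
)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_bioassay(spec: CohortSpec, rng: np.random.Generator):
    """Per-mouse defecation and propulsion records for the seven-group design.

    Loose-stool flags are Bernoulli with a dose- and sample-dependent logit;
    charcoal-faeces counts are Poisson; incubation periods and faeces weights
    are truncated normal; propulsion distances are Beta-distributed fractions
    of the intestine length (so distances never exceed lengths).
    """
    def p_loose(sample, dose):
        if sample is None:
            return spec.control_p_loose
        icpt, slope = spec.diarrhea_logit[sample]
        return _sigmoid(icpt + slope * dose)

    defecation_rows, propulsion_rows = [], []
    mouse = 0
    for group, sample, dose, n_def, n_prop in BIOASSAY_DESIGN:
        # cathartic strength index in [0, 1]: S22 about twice as potent as S10
        potency = 0.0 if sample is None else (0.10 if sample == "S10" else 0.20) * dose
        potency = min(potency, 1.0)
        p = p_loose(sample, dose)
        for _ in range(n_def):
            mouse += 1
            lam = 0.5 + 8.0 * potency
            n_feces = int(rng.poisson(lam))
            loose = bool(rng.random() < p)
            if n_feces == 0 and not loose:
                incubation = None
            else:
                n_feces = max(n_feces, 1)
                mean_inc = 280.0 - 200.0 * potency
                incubation = float(np.clip(rng.normal(mean_inc, 40.0), 10.0, 300.0))
            weight = float(max(rng.normal(2.0 + 80.0 * potency, 15.0), 0.0))
            defecation_rows.append(
                {
                    "mouse_id": f"M{mouse:03d}",
                    "group": group,
                    "dose_g_per_kg": dose,
                    "incubation_min": incubation,
                    "n_feces": n_feces,
                    "feces_mg": weight,
                    "loose": loose,
                }
            )
        for _ in range(n_prop):
            mouse += 1
            length = float(np.clip(rng.normal(44.0, 2.5), 30.0, 60.0))
            mean_frac = 0.60 + 0.22 * potency
            kappa = 60.0
            frac = float(rng.beta(mean_frac * kappa, (1 - mean_frac) * kappa))
            propulsion_rows.append(
                {
                    "mouse_id": f"M{mouse:03d}",
                    "group": group,
                    "dose_g_per_kg": dose,
                    "distance_cm": frac * length,
                    "length_cm": length,
                }
            )
    return pd.DataFrame(defecation_rows), pd.DataFrame(propulsion_rows)


def generate_cohort(spec: CohortSpec, simulate_curves: bool = True) -> SyntheticCohort:
    """Generate a complete cohort; identical spec + seed gives identical output."""
    rng = np.random.default_rng(spec.seed)
    compounds, class_totals, groups, species = generate_compounds(spec, rng)
    dl_truth, curves = generate_dl(spec, compounds, rng, simulate_curves=simulate_curves)
    peaks = generate_peaks(spec, compounds, rng)
    defecation, propulsion = generate_bioassay(spec, rng)
    return SyntheticCohort(
        spec=spec,
        compounds=compounds,
        class_totals=class_totals,
        group_labels=groups,
        species=species,
        dl_truth=dl_truth,
        dl_curves=curves,
        peak_tables=peaks,
        defecation=defecation,
        propulsion=propulsion,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write all cohort CSVs in the formats the analysis modules read."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _save(name: str, df: pd.DataFrame, index: bool) -> None:
        path = os.path.join(outdir, name)
        df.to_csv(path, index=index)
        paths[name] = path

    _save("compounds.csv", cohort.compounds.rename_axis("sample_id"), True)
    _save("class_totals.csv", cohort.class_totals.rename_axis("sample_id"), True)
    labels = pd.DataFrame(
        {"group": cohort.group_labels, "species": cohort.species}
    ).rename_axis("sample_id")
    _save("labels.csv", labels, True)
    _save("dl_truth.csv", cohort.dl_truth.rename_axis("sample_id"), True)
    _save("peaks.csv", cohort.peak_tables, False)
    _save("defecation.csv", cohort.defecation, False)
    _save("propulsion.csv", cohort.propulsion, False)
    if cohort.dl_curves:
        frames = []
        for c in cohort.dl_curves:
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": c.sample_id,
                        "replicate": c.replicate_index,
                        "time_s": c.bin_midpoints,
                        "counts": c.counts,
                    }
                )
            )
        _save("dl_curves.csv", pd.concat(frames, ignore_index=True), False)
    return paths
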