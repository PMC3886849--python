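"""Seeded synthetic fetal-sheep hypoxia-ischemia cohorts.

A cohort holds ``n_hi`` instrumented fetuses subjected to hypoxia (maternal
inspired O2 10.5%) followed by 25 min of brachiocephalic occlusion, plus an
equal number of uninstrumented twin controls.  Physiology is recorded at four
epochs (baseline, hypoxia, hypoxia-ischemia, recovery); the hypoxia-ischemia
epoch variables (cephalic BP, CaO2, glucose, lactate) are drawn jointly from
a target covariance so the printed pairwise correlations are reproduced,
and a latent injury severity — a decreasing function of a glucose-dominated
composite of BP, CaO2 and glucose — drives the GFAP and Iba1 stained area
fractions, and the necrosis burden seen by the ordinal pathology scale.

All randomness flows from a single seed; controls use an independent child
stream so their distributions never depend on the H-I covariance block.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_nearest

from . import pathology

EPOCHS = ["baseline", "hypoxia", "hypoxia_ischemia", "recovery"]
PHYS_VARS = ["BP", "HR", "pHa", "PCO2", "PO2", "Hb", "SatO2", "Hct",
             "CaO2", "glucose", "lactate"]

#: published epoch means and SDs (mean, sd); HR during hypoxia-ischemia is
#: not measurable (occluder inflated) and is emitted as missing.
EPOCH_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "baseline": {
        "BP": (34.2, 3.3), "HR": (202, 15), "pHa": (7.39, 0.02),
        "PCO2": (47.6, 3.2), "PO2": (25.0, 2.6), "Hb": (9.2, 0.8),
        "SatO2": (66.4, 5.7), "Hct": (28.6, 2.2), "CaO2": (8.2, 0.9),
        "glucose": (1.3, 0.2), "lactate": (1.4, 0.3),
    },
    "hypoxia": {
        "BP": (32.4, 3.6), "HR": (228, 36), "pHa": (7.41, 0.02),
        "PCO2": (44.6, 2.9), "PO2": (16.0, 3.3), "Hb": (9.2, 0.7),
        "SatO2": (35.0, 12.5), "Hct": (28.7, 2.2), "CaO2": (4.3, 1.6),
        "glucose": (1.2, 0.2), "lactate": (1.5, 0.3),
    },
    "hypoxia_ischemia": {
        "BP": (7.1, 2.2), "HR": (np.nan, np.nan), "pHa": (7.35, 0.03),
        "PCO2": (45.7, 3.2), "PO2": (19.3, 4.6), "Hb": (10.4, 0.9),
        "SatO2": (45.4, 15.4), "Hct": (32.1, 2.8), "CaO2": (6.0, 2.3),
        "glucose": (1.7, 0.2), "lactate": (3.6, 0.6),
    },
    "recovery": {
        "BP": (33.0, 3.3), "HR": (217, 21), "pHa": (7.31, 0.04),
        "PCO2": (47.8, 2.9), "PO2": (27.8, 2.6), "Hb": (9.7, 0.9),
        "SatO2": (69.4, 5.6), "Hct": (29.9, 2.8), "CaO2": (8.3, 0.8),
        "glucose": (1.6, 0.2), "lactate": (4.7, 0.6),
    },
}

#: signed r^2 targets among the jointly drawn hypoxia-ischemia variables.
#: CaO2/glucose/lactate pairs are the published values; the BP pairs are not
#: published and carry plausible defaults (hypotension accompanies hypoxemia
#: and metabolic stress).
HI_JOINT_VARS = ["BP", "CaO2", "glucose", "lactate"]
DEFAULT_R2_TARGETS: dict[tuple[str, str], float] = {
    ("CaO2", "lactate"): -0.74,
    ("CaO2", "glucose"): +0.30,
    ("glucose", "lactate"): -0.30,
    ("BP", "CaO2"): +0.1225,
    ("BP", "glucose"): +0.04,
    ("BP", "lactate"): -0.0625,
}

#: severity composite weights on standardized (BP, CaO2, glucose) and the
#: marker link (intercept, slope, lognormal sigma), calibrated once so the
#: replicate-mean week-adjusted r^2 profile and group means reproduce the
#: published values (see docs/methods.md). Placeholder values are replaced
#: by the committed calibration.
DEFAULT_MARKER_LINKS: dict[str, dict] = {
    "GFAP": {
        "weights": {"BP": 0.2835, "CaO2": -0.0422, "glucose": 1.0},
        "intercept": 0.4254, "slope": 0.2369, "sigma": 0.5019,
        "control_mean": 0.22, "control_sd": 0.07,
    },
    "Iba1": {
        "weights": {"BP": -0.0807, "CaO2": -0.3336, "glucose": 1.0},
        "intercept": 0.3325, "slope": 0.1021, "sigma": 0.4372,
        "control_mean": 0.16, "control_sd": 0.05,
    },
}

#: stained fractions are clipped to this physical ceiling: a section always
#: retains some unstained pixels, and the background-mode estimator is only
#: identifiable when a background mode exists.
FRACTION_CEILING = 0.92

HUFNER = 1.34       # ml O2 per g hemoglobin at full saturation
O2_SOLUBILITY = 0.003  # ml O2 per dl blood per torr of PO2


def compute_cao2(Hb: float, SatO2: float, PO2: float) -> float:
    """Arterial O2 content (ml/dl): hemoglobin-bound plus dissolved."""
    if Hb < 0 or PO2 < 0 or not 0 <= SatO2 <= 100:
        raise ValueError("Hb, PO2 must be non-negative and SatO2 in [0, 100]")
    return HUFNER * Hb * SatO2 / 100.0 + O2_SOLUBILITY * PO2


@dataclass
class EpochPhysiology:
    epoch: str
    BP: float
    HR: float
    pHa: float
    PCO2: float
    PO2: float
    Hb: float
    SatO2: float
    Hct: float
    CaO2: float
    glucose: float
    lactate: float


@dataclass
class AnimalRecord:
    animal_id: str
    group: str                    # "control" | "HI"
    survival_week: int            # 1 | 2
    severity: float
    epochs: dict[str, EpochPhysiology]
    gfap_fraction: float
    iba1_fraction: float
    necrosis_percent: float
    pathology_score: int


@dataclass
class CohortConfig:
    n_hi: int = 17
    n_week1: int = 10
    epoch_stats: dict = field(default_factory=lambda: copy.deepcopy(EPOCH_STATS))
    r2_targets: dict = field(default_factory=lambda: dict(DEFAULT_R2_TARGETS))
    marker_links: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_MARKER_LINKS))
    pathology_threshold: float = pathology.DEFAULT_THRESHOLD
    pathology_gain: float = pathology.DEFAULT_GAIN
    pathology_noise_sd: float = pathology.DEFAULT_NOISE_SD
    fraction_ceiling: float = FRACTION_CEILING
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_week1 > self.n_hi:
            raise ValueError("n_week1 cannot exceed n_hi")


class InfeasibleCorrelationError(ValueError):
    """Raised when the target correlations cannot be met by a PD matrix."""


def build_covariance(
    r2_targets: dict[tuple[str, str], float],
    sds: dict[str, float],
    order: list[str] | None = None,
    max_projection_change: float = 0.05,
) -> tuple[np.ndarray, list[str], float]:
    """Covariance matrix realizing signed-r^2 pairwise targets.

    Off-diagonal correlations are ``sign(r2) * sqrt(|r2|)``; if the resulting
    matrix is not positive definite it is projected to the nearest
    correlation matrix.  A projection that moves any targeted correlation by
    more than ``max_projection_change`` raises, naming the offending pairs.

    Returns (covariance, variable order, max projection change).
    """
    if order is None:
        order = sorted(sds)
    k = len(order)
    corr = np.eye(k)
    for (a, b), r2 in r2_targets.items():
        if abs(r2) > 1:
            raise InfeasibleCorrelationError(f"|r2| > 1 for pair ({a}, {b})")
        i, j = order.index(a), order.index(b)
        rho = np.sign(r2) * np.sqrt(abs(r2))
        corr[i, j] = corr[j, i] = rho
    eigvals = np.linalg.eigvalsh(corr)
    max_change = 0.0
    if eigvals.min() <= 1e-10:
        projected = corr_nearest(corr, threshold=1e-8, n_fact=1000)
        delta = np.abs(projected - corr)
        max_change = float(delta.max())
        if max_change > max_projection_change:
            bad = [
                (order[i], order[j], float(delta[i, j]))
                for i in range(k) for j in range(i + 1, k)
                if delta[i, j] > max_projection_change
            ]
            raise InfeasibleCorrelationError(
                f"infeasible correlation targets; projection moved pairs: {bad}"
            )
        corr = projected
    sd_vec = np.array([sds[v] for v in order], dtype=float)
    cov = corr * np.outer(sd_vec, sd_vec)
    return cov, order, max_change


def _severity_norm(weights: dict[str, float], corr: np.ndarray,
                   order: list[str]) -> float:
    w = np.array([weights.get(v, 0.0) for v in order])
    return float(np.sqrt(w @ corr @ w))


def composite_severity(
    z: dict[str, np.ndarray], weights: dict[str, float],
    corr: np.ndarray, order: list[str],
) -> np.ndarray:
    """Standardized decreasing composite of the H-I epoch z-scores."""
    norm = _severity_norm(weights, corr, order)
    s = -sum(weights.get(v, 0.0) * z[v] for v in order if v in z)
    return np.asarray(s) / norm


def _lognormal_factor(rng: np.random.Generator, sigma: float, size: int):
    """Multiplicative noise with unit mean."""
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _moment_matched_lognormal(rng, mean, sd, size):
    if sd == 0:
        return np.full(size, mean)
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def generate_cohort(config: CohortConfig) -> list[AnimalRecord]:
    """Draw one full cohort (H-I animals + twin controls), deterministic per seed."""
    ss = np.random.SeedSequence(config.seed)
    rng_hi, rng_ctrl, rng_path = (np.random.default_rng(s) for s in ss.spawn(3))
    n = config.n_hi
    stats = config.epoch_stats
    clip_events: list[str] = []

    # --- jointly drawn hypoxia-ischemia block -----------------------------
    hi_sds = {v: stats["hypoxia_ischemia"][v][1] for v in HI_JOINT_VARS}
    hi_means = {v: stats["hypoxia_ischemia"][v][0] for v in HI_JOINT_VARS}
    if all(sd == 0 for sd in hi_sds.values()):
        joint = {v: np.full(n, hi_means[v]) for v in HI_JOINT_VARS}
        corr = np.eye(len(HI_JOINT_VARS))
        order = list(HI_JOINT_VARS)
    else:
        cov, order, _ = build_covariance(config.r2_targets, hi_sds,
                                         order=list(HI_JOINT_VARS))
        mean_vec = np.array([hi_means[v] for v in order])
        draws = rng_hi.multivariate_normal(mean_vec, cov, size=n,
                                           method="cholesky")
        joint = {v: draws[:, i] for i, v in enumerate(order)}
        sd_vec = np.array([hi_sds[v] for v in order])
        corr = cov / np.outer(sd_vec, sd_vec)
    # physical floors
    for v in HI_JOINT_VARS:
        lo = np.clip(joint[v], 0.0, None)
        if np.any(lo != joint[v]):
            clip_events.append(f"HI {v} clipped at 0")
        joint[v] = lo

    # --- per-epoch independent physiology ---------------------------------
    epoch_values: dict[str, dict[str, np.ndarray]] = {}
    for epoch in EPOCHS:
        vals: dict[str, np.ndarray] = {}
        for v in PHYS_VARS:
            if v == "SatO2":
                continue  # derived below
            mean, sd = stats[epoch][v]
            if epoch == "hypoxia_ischemia" and v in HI_JOINT_VARS:
                vals[v] = joint[v]
            elif np.isnan(mean):
                vals[v] = np.full(n, np.nan)
            else:
                vals[v] = mean + sd * rng_hi.standard_normal(n)
        epoch_values[epoch] = vals
    # recovery glucose/lactate inherit the within-animal rank of the H-I draw
    for v in ("glucose", "lactate"):
        draws = np.sort(epoch_values["recovery"][v])
        ranks = np.argsort(np.argsort(epoch_values["hypoxia_ischemia"][v]))
        epoch_values["recovery"][v] = draws[ranks]
    # SatO2 derived from CaO2, Hb, PO2 so the O2-content identity holds
    for epoch in EPOCHS:
        vals = epoch_values[epoch]
        sat = (vals["CaO2"] - O2_SOLUBILITY * vals["PO2"]) / (HUFNER * vals["Hb"]) * 100.0
        clipped = np.clip(sat, 0.0, 100.0)
        if np.any(clipped != sat):
            clip_events.append(f"{epoch} SatO2 clipped to [0, 100]")
            vals["CaO2"] = HUFNER * vals["Hb"] * clipped / 100.0 \
                + O2_SOLUBILITY * vals["PO2"]
        vals["SatO2"] = clipped

    # --- latent severity and marker links ---------------------------------
    z = {
        v: (joint[v] - hi_means[v]) / hi_sds[v] if hi_sds[v] > 0
        else np.zeros(n)
        for v in ("BP", "CaO2", "glucose")
    }
    sub = [order.index(v) for v in ("BP", "CaO2", "glucose")]
    corr3 = corr[np.ix_(sub, sub)]
    fractions: dict[str, np.ndarray] = {}
    severities: dict[str, np.ndarray] = {}
    for marker, link in config.marker_links.items():
        s = composite_severity(z, link["weights"], corr3, ["BP", "CaO2", "glucose"])
        noise = _lognormal_factor(rng_hi, link["sigma"], n)
        raw = (link["intercept"] + link["slope"] * s) * noise
        frac = np.clip(raw, 0.0, config.fraction_ceiling)
        if np.any(frac != raw):
            clip_events.append(f"HI {marker} fraction clipped")
        fractions[marker] = frac
        severities[marker] = s
    severity = severities["GFAP"]  # primary latent injury scale

    # --- pathology ---------------------------------------------------------
    percents, scores = pathology.score_animals(
        severity, seed=int(rng_path.integers(0, 2**31 - 1)),
        threshold=config.pathology_threshold, gain=config.pathology_gain,
        noise_sd=config.pathology_noise_sd,
    )

    # --- assemble H-I animals ----------------------------------------------
    animals: list[AnimalRecord] = []
    for i in range(n):
        epochs = {
            e: EpochPhysiology(epoch=e, **{v: float(epoch_values[e][v][i])
                                           for v in PHYS_VARS})
            for e in EPOCHS
        }
        animals.append(AnimalRecord(
            animal_id=f"HI{i + 1:02d}", group="HI",
            survival_week=1 if i < config.n_week1 else 2,
            severity=float(severity[i]), epochs=epochs,
            gfap_fraction=float(fractions["GFAP"][i]),
            iba1_fraction=float(fractions["Iba1"][i]),
            necrosis_percent=float(percents[i]),
            pathology_score=int(scores[i]),
        ))

    # --- twin controls: baseline physiology only, no injury links ----------
    ctrl_frac = {
        marker: np.clip(
            _moment_matched_lognormal(
                rng_ctrl, link["control_mean"], link["control_sd"], n),
            0.0, config.fraction_ceiling)
        for marker, link in config.marker_links.items()
    }
    base = stats["baseline"]
    for i in range(n):
        vals = {}
        for v in PHYS_VARS:
            mean, sd = base[v]
            if v == "SatO2":
                continue
            vals[v] = float(mean + sd * rng_ctrl.standard_normal())
        sat = (vals["CaO2"] - O2_SOLUBILITY * vals["PO2"]) / (HUFNER * vals["Hb"]) * 100.0
        vals["SatO2"] = float(np.clip(sat, 0.0, 100.0))
        if vals["SatO2"] != sat:
            vals["CaO2"] = compute_cao2(vals["Hb"], vals["SatO2"], vals["PO2"])
        epochs = {"baseline": EpochPhysiology(epoch="baseline", **vals)}
        animals.append(AnimalRecord(
            animal_id=f"C{i + 1:02d}", group="control",
            survival_week=1 if i < config.n_week1 else 2,
            severity=0.0, epochs=epochs,
            gfap_fraction=float(ctrl_frac["GFAP"][i]),
            iba1_fraction=float(ctrl_frac["Iba1"][i]),
            necrosis_percent=0.0, pathology_score=0,
        ))
    generate_cohort.last_clip_events = clip_events  # type: ignore[attr-defined]
    return animals


# ---------------------------------------------------------------------------
# CSV round trip: long epoch table + per-animal summary table

SUMMARY_COLUMNS = ["animal_id", "group", "survival_week", "severity",
                   "gfap_fraction", "iba1_fraction", "necrosis_percent",
                   "pathology_score"]
EPOCH_COLUMNS = ["animal_id", "epoch"] + PHYS_VARS


def cohort_to_frames(cohort: list[AnimalRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    epoch_rows, summary_rows = [], []
    for a in cohort:
        summary_rows.append({k: getattr(a, k) for k in SUMMARY_COLUMNS})
        for e, phys in a.epochs.items():
            row = asdict(phys)
            row["animal_id"] = a.animal_id
            epoch_rows.append(row)
    epochs = pd.DataFrame(epoch_rows, columns=EPOCH_COLUMNS)
    summary = pd.DataFrame(summary_rows, columns=SUMMARY_COLUMNS)
    return epochs, summary


def write_cohort_csv(cohort: list[AnimalRecord], epochs_path: str | Path,
                     summary_path: str | Path) -> None:
    epochs, summary = cohort_to_frames(cohort)
    epochs.to_csv(epochs_path, index=False)
    summary.to_csv(summary_path, index=False)


def read_cohort_csv(epochs_path: str | Path,
                    summary_path: str | Path) -> list[AnimalRecord]:
    epochs = pd.read_csv(epochs_path)
    summary = pd.read_csv(summary_path)
    for df, cols, name in ((epochs, EPOCH_COLUMNS, "epoch table"),
                           (summary, SUMMARY_COLUMNS, "summary table")):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{name} missing columns: {sorted(missing)}")
    cohort = []
    for _, row in summary.iterrows():
        sub = epochs[epochs.animal_id == row.animal_id]
        eps = {
            r.epoch: EpochPhysiology(epoch=r.epoch,
                                     **{v: float(getattr(r, v)) for v in PHYS_VARS})
            for r in sub.itertuples()
        }
        cohort.append(AnimalRecord(
            animal_id=row.animal_id, group=row.group,
            survival_week=int(row.survival_week), severity=float(row.severity),
            epochs=eps, gfap_fraction=float(row.gfap_fraction),
            iba1_fraction=float(row.iba1_fraction),
            necrosis_percent=float(row.necrosis_percent),
            pathology_score=int(row.pathology_score),
        ))
    return cohort
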