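"""End-to-end desk-scale study orchestration.

simulate cohort -> synthesize section images -> quantify stained fractions
-> score pathology -> run associations -> emit report.  One top-level seed
fans out to per-stage child streams, so reruns with the same config are
byte-identical; the run manifest records per-stage outputs, checksums and
warnings (clamped fractions, degenerate histograms, clip events).
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import areafrac, assoc, synth_images
from .cohort import (
    CohortConfig, EPOCH_STATS, FRACTION_CEILING, cohort_to_frames,
    generate_cohort, write_cohort_csv,
)

#: recovered-vs-target comparisons reported by the summary; each entry is
#: (label, target value).
CALIBRATION_TARGETS = {
    "gfap_fraction_hi": 0.40,
    "gfap_fraction_control": 0.22,
    "iba1_fraction_hi": 0.33,
    "iba1_fraction_control": 0.16,
    "bp_hi_epoch": 7.1,
    "glucose_baseline": 1.3,
    "r2_glucose_gfap": 0.499,
    "r2_cao2_gfap": 0.21,
    "r2_bp_gfap": 0.15,
    "r2_lactate_cao2": 0.74,
    "score0_count": 12,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    n_hi: int = 17
    n_week1: int = 10
    n_sections: int = 3
    image_width: int = 512
    image_height: int = 512
    bit_depth: int = 8
    section_jitter_sd: float = synth_images.DEFAULT_SECTION_JITTER_SD
    skip_images: bool = False
    write_images: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(n_hi=self.n_hi, n_week1=self.n_week1,
                            seed=_child_seed(self.seed, 0))


@dataclass
class RunManifest:
    config: dict
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)
    self_check: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _child_seed(seed: int, stage: int) -> int:
    # fixed per-stage offsets keep stages independent yet reproducible
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def quantify_animal_images(
    cohort, *, seed: int, n_sections: int = 3, width: int = 512,
    height: int = 512, bit_depth: int = 8,
    jitter_sd: float = synth_images.DEFAULT_SECTION_JITTER_SD,
    out_dir: Path | None = None,
) -> pd.DataFrame:
    """Imaging + quantification stages, in memory.

    For every animal and marker, renders triplicate sections whose true
    fraction is the animal's realized marker fraction (plus section jitter)
    and runs the histogram-reflection estimator on each.  If ``out_dir`` is
    given the images, masks and a manifest CSV are also written.
    """
    rng = np.random.default_rng(seed)
    manifest = synth_images.ImageManifest()
    rows = []
    for animal in cohort:
        for marker, frac in (("GFAP", animal.gfap_fraction),
                             ("Iba1", animal.iba1_fraction)):
            images = synth_images.generate_animal_sections(
                severity=animal.severity, marker=marker,
                calib=lambda s, f=frac: f,
                seed=int(rng.integers(0, 2**31 - 1)),
                n_sections=n_sections, jitter_sd=jitter_sd,
                max_fraction=FRACTION_CEILING,
                width=width, height=height, bit_depth=bit_depth,
            )
            fracs = []
            for k, img in enumerate(images):
                f, bg = areafrac.labeled_area_fraction_detailed(img)
                fracs.append(f)
                path = ""
                if out_dir is not None:
                    path = str(out_dir / f"{animal.animal_id}_{marker}_s{k}.tif")
                    synth_images.save_image(img, path)
                    manifest.add(animal.animal_id, marker, k,
                                 img.truth_fraction, path)
                rows.append(dict(
                    animal_id=animal.animal_id, marker=marker, section_index=k,
                    true_fraction=img.truth_fraction, fraction=f,
                    degenerate_flag=bg.degenerate, clamp_flag=bg.clamp_applied,
                ))
            animal_frac = areafrac.animal_area_fraction(fracs, marker).animal_fraction
            for r in rows[-n_sections:]:
                r["animal_fraction"] = animal_frac
    df = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.write(out_dir / "image_manifest.csv")
    return df


def quantify_manifest(manifest_path: str | Path, bit_depth: int = 8) -> pd.DataFrame:
    """Quantify previously written section images listed in a manifest CSV."""
    manifest = synth_images.ImageManifest.read(manifest_path)
    rows = []
    for row in manifest.rows:
        img = synth_images.load_image(row["path"],
                                      row["roi_path"] or None, bit_depth)
        f, bg = areafrac.labeled_area_fraction_detailed(img)
        rows.append(dict(
            animal_id=row["animal_id"], marker=row["marker"],
            section_index=row["section_index"],
            true_fraction=row["true_fraction"], fraction=f,
            degenerate_flag=bg.degenerate, clamp_flag=bg.clamp_applied,
        ))
    df = pd.DataFrame(rows)
    df["animal_fraction"] = df.groupby(["animal_id", "marker"])["fraction"].transform("mean")
    return df


def run_associations(summary: pd.DataFrame, epochs: pd.DataFrame) -> dict:
    """Association stage: predictor profile, metabolic pairs, group tests."""
    hi = summary[summary.group == "HI"]
    ctrl = summary[summary.group == "control"]
    hie = epochs[epochs.epoch == "hypoxia_ischemia"].set_index("animal_id")
    hie = hie.loc[hi.animal_id]
    wk = hi.survival_week.to_numpy()
    profile = assoc.multi_predictor_profile(summary, epochs)
    low_n = len(hi) < 10
    metabolic = {}
    for name, (x, y) in {
        "lactate_vs_cao2": (hie.lactate, hie.CaO2),
        "glucose_vs_cao2": (hie.glucose, hie.CaO2),
        "glucose_vs_lactate": (hie.glucose, hie.lactate),
    }.items():
        res = assoc.adjusted_linear_assoc(x.to_numpy(), y.to_numpy(), wk,
                                          predictor=name.split("_vs_")[0],
                                          outcome=name.split("_vs_")[1])
        metabolic[name] = vars(res)
    groups = {}
    for marker, col in assoc.OUTCOMES.items():
        F, p, degen = assoc.two_group_f_test(hi[col], ctrl[col])
        groups[marker] = dict(F=F, p=p, degenerate=degen)
    return dict(profile=profile, metabolic=metabolic, group_tests=groups,
                low_n_flag=low_n)


def run_pipeline(
    config: PipelineConfig | str | Path, out_dir: str | Path,
) -> RunManifest:
    """Run the full study into ``out_dir`` and return the manifest."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), seed=config.seed)

    def _record(name: str, path: Path) -> None:
        manifest.outputs[name] = str(path)
        manifest.checksums[name] = _sha256(path)

    # stage 1: cohort simulation ------------------------------------------
    t0 = time.perf_counter()
    try:
        cohort = generate_cohort(config.cohort_config())
    except Exception as err:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'simulate' failed: {err}") from err
    epochs, summary = cohort_to_frames(cohort)
    write_cohort_csv(cohort, out / "cohort_epochs.csv", out / "cohort_summary.csv")
    _record("cohort_epochs", out / "cohort_epochs.csv")
    _record("cohort_summary", out / "cohort_summary.csv")
    manifest.warnings.extend(getattr(generate_cohort, "last_clip_events", []))
    manifest.timings["simulate"] = time.perf_counter() - t0

    # stage 2+3: imaging and quantification --------------------------------
    t0 = time.perf_counter()
    if config.skip_images:
        # fractions taken directly from the generator's realized values
        rows = []
        for a in cohort:
            for marker, frac in (("GFAP", a.gfap_fraction), ("Iba1", a.iba1_fraction)):
                rows.append(dict(animal_id=a.animal_id, marker=marker,
                                 section_index=0, true_fraction=frac,
                                 fraction=frac, degenerate_flag=False,
                                 clamp_flag=False, animal_fraction=frac))
        fractions = pd.DataFrame(rows)
    else:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        try:
            fractions = quantify_animal_images(
                cohort, seed=_child_seed(config.seed, 1),
                n_sections=config.n_sections, width=config.image_width,
                height=config.image_height, bit_depth=config.bit_depth,
                jitter_sd=config.section_jitter_sd,
                out_dir=img_dir if config.write_images else None,
            )
        except Exception as err:
            raise RuntimeError(f"stage 'quantify' failed: {err}") from err
        if config.write_images:
            _record("image_manifest", img_dir / "image_manifest.csv")
        n_deg = int(fractions.degenerate_flag.sum())
        n_clamp = int(fractions.clamp_flag.sum())
        if n_deg:
            manifest.warnings.append(f"{n_deg} degenerate section histograms")
        if n_clamp:
            manifest.warnings.append(f"{n_clamp} clamped background estimates")
    fractions.to_csv(out / "fractions.csv", index=False)
    _record("fractions", out / "fractions.csv")
    manifest.timings["quantify"] = time.perf_counter() - t0

    # measured per-animal fractions replace the generator's in the analysis
    analysed = summary.copy()
    for marker, col in (("GFAP", "gfap_fraction"), ("Iba1", "iba1_fraction")):
        per_animal = (fractions[fractions.marker == marker]
                      .groupby("animal_id")["animal_fraction"].first())
        analysed[col] = analysed.animal_id.map(per_animal)

    # stage 4: associations -------------------------------------------------
    t0 = time.perf_counter()
    try:
        results = run_associations(analysed, epochs)
    except Exception as err:
        raise RuntimeError(f"stage 'analyze' failed: {err}") from err
    results["profile"].to_csv(out / "associations.csv", index=False)
    _record("associations", out / "associations.csv")
    ranking = (results["profile"].sort_values(["outcome", "rank"])
               [["outcome", "predictor", "r2", "p", "rank"]].to_dict("records"))
    with open(out / "associations.json", "w") as fh:
        json.dump(dict(ranking=ranking, metabolic=results["metabolic"],
                       group_tests=results["group_tests"],
                       low_n_flag=results["low_n_flag"]), fh, indent=2,
                  sort_keys=True)
    _record("associations_json", out / "associations.json")
    if results["low_n_flag"]:
        manifest.warnings.append("low-n cohort: associations underpowered")
    manifest.timings["analyze"] = time.perf_counter() - t0

    # self-check: replicate-mean calibration moments within 20% of targets --
    t0 = time.perf_counter()
    # the calibration gate always runs at the default study size: it checks
    # the generator's calibration, not the luck of this particular cohort
    manifest.self_check = dict(
        single_run=recovered_quantities(analysed, epochs, results),
        calibration=calibration_self_check(seed=_child_seed(config.seed, 2)),
    )
    manifest.timings["self_check"] = time.perf_counter() - t0
    manifest.write(out / "run_manifest.json")
    if not manifest.self_check["calibration"]["passed"]:
        raise RuntimeError("stage 'self_check' failed: calibration moments "
                           "off target by more than 20%")
    return manifest


def recovered_quantities(summary: pd.DataFrame, epochs: pd.DataFrame,
                         results: dict) -> dict[str, float]:
    """Recovered values of the calibration quantities from one run."""
    hi = summary[summary.group == "HI"]
    ctrl = summary[summary.group == "control"]
    prof = results["profile"].set_index(["predictor", "outcome"])
    return {
        "gfap_fraction_hi": float(hi.gfap_fraction.mean()),
        "gfap_fraction_control": float(ctrl.gfap_fraction.mean()),
        "iba1_fraction_hi": float(hi.iba1_fraction.mean()),
        "iba1_fraction_control": float(ctrl.iba1_fraction.mean()),
        "bp_hi_epoch": float(epochs[epochs.epoch == "hypoxia_ischemia"]
                             .set_index("animal_id").loc[hi.animal_id].BP.mean()),
        "glucose_baseline": float(epochs[epochs.epoch == "baseline"].glucose.mean()),
        "r2_glucose_gfap": float(prof.loc[("glucose", "GFAP"), "r2"]),
        "r2_cao2_gfap": float(prof.loc[("CaO2", "GFAP"), "r2"]),
        "r2_bp_gfap": float(prof.loc[("BP", "GFAP"), "r2"]),
        "r2_lactate_cao2": float(results["metabolic"]["lactate_vs_cao2"]["r2"]),
        "score0_count": int((hi.pathology_score == 0).sum()),
    }


def calibration_self_check(seed: int, n_cohorts: int = 100, n_hi: int = 17,
                           n_week1: int = 10, tolerance: float = 0.20) -> dict:
    """Replicate-mean recovered-vs-target gate for the generator calibration.

    A single n=17 cohort is far too noisy to gate on, so the check averages
    fresh replicate cohorts; any replicate-mean quantity off its target by
    more than ``tolerance`` (with an absolute floor of 0.05, the natural
    scale for the r-squared targets) fails the run.
    """
    acc: dict[str, list] = {k: [] for k in CALIBRATION_TARGETS}
    for m in range(n_cohorts):
        cohort = generate_cohort(CohortConfig(
            n_hi=n_hi, n_week1=min(n_week1, n_hi), seed=seed + m))
        epochs, summary = cohort_to_frames(cohort)
        results = run_associations(summary, epochs)
        rec = recovered_quantities(summary, epochs, results)
        for k in acc:
            acc[k].append(rec[k])
    report: dict = {}
    for key, target in CALIBRATION_TARGETS.items():
        got = float(np.median(acc[key]) if key == "score0_count"
                    else np.mean(acc[key]))
        tol = max(tolerance * abs(target), 0.05)
        report[key] = dict(target=target, recovered=got,
                           ok=bool(abs(got - target) <= tol))
    report["passed"] = all(v["ok"] for v in report.values()
                           if isinstance(v, dict))
    return report


def report_summary(manifest: RunManifest) -> str:
    """Human-readable recovered-vs-target tabulation for a completed run."""
    if not manifest.outputs:
        raise ValueError("empty manifest: no completed stages to report")
    lines = [
        "gliaquant run summary",
        "=====================",
        f"seed: {manifest.seed}",
        "",
        f"{'quantity':26s}{'target':>10s}{'recovered':>12s}",
    ]
    single = manifest.self_check.get("single_run", {})
    for key, target in CALIBRATION_TARGETS.items():
        if key in single:
            lines.append(f"{key:26s}{target:10.3f}{single[key]:12.3f}")
        else:
            lines.append(f"{key:26s}{target:10.3f}{'missing':>12s}")
    calib = manifest.self_check.get("calibration", {})
    if calib:
        lines.append("")
        lines.append(f"replicate calibration self-check: "
                     f"{'PASS' if calib.get('passed') else 'FAIL'}")
    if "fractions" not in manifest.outputs:
        lines.append("imaging/quantification stage: MISSING")
    lines.append("")
    hi_scores = None
    if "cohort_summary" in manifest.outputs:
        p = Path(manifest.outputs["cohort_summary"])
        if p.exists():
            su = pd.read_csv(p)
            hi = su[su.group == "HI"]
            hi_scores = hi
    if hi_scores is not None:
        zero = hi_scores[hi_scores.pathology_score == 0]
        rng_all = np.ptp(hi_scores.gfap_fraction)
        span = np.ptp(zero.gfap_fraction) / rng_all if rng_all > 0 else np.nan
        lines.append(f"score-0 animals: {len(zero)}/{len(hi_scores)}; "
                     f"they span {span:.0%} of the H-I GFAP fraction range")
    if manifest.warnings:
        lines.append("")
        lines.append("warnings:")
        lines.extend(f"  - {w}" for w in manifest.warnings)
    return "\n".join(lines)
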