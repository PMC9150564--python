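"""End-to-end study orchestration: simulation -> reconstruction -> statistics.

One global seed is expanded into independent per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn`` in a fixed, documented order
(phantom noise, demographics, ROI values, maps), so a single integer makes
every stage reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as ch
from . import io as hio
from . import roc as rc
from . import stats as stt
from .core import GridSpec, PhysicsConfig
from .phantom import (
    Disk,
    birdcage_field,
    combine_echoes,
    derive_hplus,
    make_phantom,
    solve_forward_ez,
    synthesize_echoes,
)
from .recon import (
    evaluate_recon,
    reconstruct_cr_mrept,
    reconstruct_phase_based,
    reconstruct_std_mrept,
    unwrap,
)

__all__ = ["RunConfig", "stage_seeds", "run_phantom_study", "run_cohort_study"]

#: fixed stage order for seed spawning
_STAGES = ("echo_noise", "demographics", "roi_values", "maps")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds (< 2**31) from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, c in zip(_STAGES, children)
    }


@dataclass
class RunConfig:
    """Single configuration object governing a full run."""

    seed: int = 0
    out_dir: str = "results"
    # phantom / physics
    nx: int = 128
    ny: int = 128
    dx: float = 0.0012
    dy: float = 0.0012
    b0_tesla: float = 3.0
    head_radius: float = 0.07
    head_sigma: float = 0.34  # WM-like background, S/m
    head_eps_r: float = 52.0
    inclusion_radius: float = 0.04
    inclusion_center: tuple = (0.012, 0.0)
    inclusion_sigma: float = 0.59  # GM-like inclusion
    inclusion_eps_r: float = 73.0
    # acquisition
    te_ms: tuple = (12, 24, 36, 48, 60, 72)
    t2_ms: float = 80.0
    snr: float = float("inf")
    # reconstruction
    c_diff: float | None = None
    fwhm_mm: float = 0.0
    erosion_px: int = 3
    # cohort
    n_per_group: tuple = (24, 27, 23)
    alpha: float = 0.05

    def grid(self) -> GridSpec:
        return GridSpec(self.nx, self.ny, self.dx, self.dy)

    def physics(self) -> PhysicsConfig:
        return PhysicsConfig(b0_tesla=self.b0_tesla)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("te_ms", "n_per_group", "inclusion_center"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _two_compartment(config: RunConfig):
    grid = config.grid()
    return make_phantom(
        grid,
        [
            (Disk(0.0, 0.0, config.head_radius), config.head_sigma, config.head_eps_r, 1),
            (
                Disk(*config.inclusion_center, config.inclusion_radius),
                config.inclusion_sigma,
                config.inclusion_eps_r,
                2,
            ),
        ],
    )


def run_phantom_study(config: RunConfig) -> dict:
    """Phantom -> forward field -> echoes -> three reconstructions -> report.

    Writes the phantom, field, combined phase, reconstructions, an error
    table (CSV) and a provenance sidecar into ``config.out_dir``.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    grid, physics = config.grid(), config.physics()

    stage = "phantom"
    try:
        phantom = _two_compartment(config)
        mask = phantom.object_mask()

        stage = "forward"
        illum = birdcage_field(
            grid, physics, phantom.sigma[mask].mean(), phantom.eps_r[mask].mean()
        )
        ez = solve_forward_ez(phantom, physics, illum)
        hplus = derive_hplus(ez, physics)

        stage = "echoes"
        echoes = synthesize_echoes(
            hplus, config.te_ms, config.t2_ms, config.snr, seeds["echo_noise"]
        )
        phase, mag = combine_echoes(echoes)
        phase_tr = unwrap(phase)
        u_est = dataclasses.replace(hplus, values=mag * np.exp(1j * phase_tr / 2.0))

        stage = "reconstruction"
        recons = {
            "phase": reconstruct_phase_based(phase_tr, grid, physics, mask=mask),
            "std": reconstruct_std_mrept(u_est, physics, mask=mask),
            "cr": reconstruct_cr_mrept(u_est, physics, c_diff=config.c_diff, mask=mask),
        }

        stage = "evaluation"
        rows = []
        for name, r in recons.items():
            rep = evaluate_recon(r, phantom, erosion_px=config.erosion_px)
            rows.append(
                dict(
                    method=name,
                    mae=rep.mae,
                    rmse=rep.rmse,
                    median_rel_err_pct=rep.median_rel_err_pct,
                    **{f"median_label{k}": v for k, v in rep.per_label_median.items()},
                )
            )
        report = pd.DataFrame(rows)
    except Exception as exc:
        raise RuntimeError(f"phantom study failed at stage {stage!r}: {exc}") from exc

    hio.save_map(phantom.sigma, grid, out / "phantom_sigma.nii.gz")
    hio.save_map(phantom.labels.astype(float), grid, out / "phantom_labels.nii.gz")
    hio.save_complex(hplus.values, grid, out / "hplus")
    hio.save_map(phase_tr, grid, out / "phase_tr.nii.gz")
    for name, r in recons.items():
        hio.save_map(np.nan_to_num(r.sigma), grid, out / f"recon_{name}.nii.gz")
    report.to_csv(out / "recon_report.csv", index=False, float_format="%.8g")
    hio.write_sidecar(
        out / "phantom_study.json",
        config=config,
        seeds=seeds,
        runtime_s=round(time.time() - t0, 3),
        cr_params=recons["cr"].params,
    )
    return {"report": report, "recons": recons, "phantom": phantom}


def _table2_style(values: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Kruskal-Wallis + Conover per ROI x measure, printed-table layout."""
    rows = []
    for (roi, meas), sub in values.groupby(["roi", "measure"], sort=False):
        groups = [sub.loc[sub.group == g, "value"].to_numpy() for g in ch.GROUPS]
        res = stt.conover_posthoc(groups, alpha=alpha)
        med = {g: float(np.median(v)) for g, v in zip(ch.GROUPS, groups)}
        rows.append(
            dict(
                roi=roi,
                measure=meas,
                **{f"median_{g}": med[g] for g in ch.GROUPS},
                kw_h=res.statistic,
                kw_p=res.pvalue,
                significant_pairs=";".join(
                    f"({i + 1},{j + 1})" for i, j in res.significant_pairs
                ),
            )
        )
    return pd.DataFrame(rows)


def _table3_style(values: pd.DataFrame) -> pd.DataFrame:
    """Spearman vs age and age-adjusted partial correlation vs MMSE."""
    rows = []
    for (roi, meas), sub in values.groupby(["roi", "measure"], sort=False):
        sp = stt.spearman(sub["age"], sub["value"])
        pc = stt.partial_correlation(sub["value"], sub["mmse"], sub["age"])
        rows.append(
            dict(roi=roi, measure=meas, age_rho=sp.statistic, age_p=sp.pvalue,
                 adjmmse_r=pc.statistic, adjmmse_p=pc.pvalue)
        )
    return pd.DataFrame(rows)


def _table4_style(values: pd.DataFrame) -> pd.DataFrame:
    """ROC added-value table: single markers and logistic combinations."""
    wide = values.pivot_table(
        index=["id", "group"], columns=["roi", "measure"], values="value"
    )
    markers = {
        "hippo_gmv": wide[("hippocampus", "GMV")],
        "hippo_wmv": wide[("hippocampus", "WMV")],
        "insula_hfc": wide[("insula", "HFC")],
    }
    combos = {
        "hippo_gmv": ["hippo_gmv"],
        "hippo_wmv": ["hippo_wmv"],
        "insula_hfc": ["insula_hfc"],
        "gmv+wmv": ["hippo_gmv", "hippo_wmv"],
        "gmv+insula_hfc": ["hippo_gmv", "insula_hfc"],
        "wmv+insula_hfc": ["hippo_wmv", "insula_hfc"],
        "gmv+wmv+insula_hfc": ["hippo_gmv", "hippo_wmv", "insula_hfc"],
    }
    contrasts = [("CN", "MCI"), ("CN", "AD"), ("MCI", "AD")]
    grp = wide.index.get_level_values("group")
    rows = []
    for name, cols in combos.items():
        row: dict = {"markers": name}
        for neg, pos in contrasts:
            sel = (grp == neg) | (grp == pos)
            y = (grp[sel] == pos).astype(int)
            X = np.column_stack([markers[c][sel] for c in cols])
            r = rc.combined_roc(X, y) if len(cols) > 1 else rc.single_marker_roc(X[:, 0], y)
            tag = f"{neg}_vs_{pos}"
            row[f"{tag}_se"] = r.sensitivity
            row[f"{tag}_sp"] = r.specificity
            row[f"{tag}_auc"] = r.auc
            row[f"{tag}_p"] = r.pvalue
        rows.append(row)
    return pd.DataFrame(rows)


def run_cohort_study(config: RunConfig, effect: ch.EffectSpec | None = None) -> dict:
    """Cohort simulation plus the full ROI statistical battery.

    Writes the subject table, per-ROI group comparison, correlation and ROC
    tables (CSV) plus a provenance sidecar into ``config.out_dir``.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    stage = "demographics"
    try:
        subjects = ch.simulate_demographics(config.n_per_group, seed=seeds["demographics"])
        stage = "roi_values"
        values = ch.simulate_roi_values(subjects, effect, seed=seeds["roi_values"])
        stage = "group_comparison"
        table2 = _table2_style(values, config.alpha)
        stage = "correlations"
        table3 = _table3_style(values)
        stage = "roc"
        table4 = _table4_style(values)
    except Exception as exc:
        raise RuntimeError(f"cohort study failed at stage {stage!r}: {exc}") from exc

    subjects.to_csv(out / "subjects.csv", index=False, float_format="%.8g")
    values.to_csv(out / "roi_values.csv", index=False, float_format="%.8g")
    table2.to_csv(out / "group_comparison.csv", index=False, float_format="%.8g")
    table3.to_csv(out / "correlations.csv", index=False, float_format="%.8g")
    table4.to_csv(out / "roc_added_value.csv", index=False, float_format="%.8g")
    hio.write_sidecar(
        out / "cohort_study.json",
        config=config,
        seeds=seeds,
        runtime_s=round(time.time() - t0, 3),
    )
    return {
        "subjects": subjects,
        "values": values,
        "group_comparison": table2,
        "correlations": table3,
        "roc": table4,
    }
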