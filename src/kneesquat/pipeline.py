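"""Scenario orchestration: PCL-release comparison runs, reports, plots, config I/O.

A scenario is one force-controlled squat of the default synthetic knee with a
given PCL stiffness release.  The release comparison runs the unreleased, 50 %
and 75 % released models under identical boundary conditions (verified by a
config diff before running — the three scenarios may differ in nothing but the
release percentage) and reports the descriptive outputs of interest:
quadriceps force, AP tibial translation, von Mises stress on inlay and
patellar cartilage, and collateral ligament load curves.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import tissue as _tissue
from .control import ControllerConfig, GrfBand
from .geometry import GeometryParams
from .solver import DEFAULT_FLEXION_CAP, KneeModel, SquatSchedule, SquatTrace, run_squat

SCHEMA_VERSION = 1

#: scalar geometry fields that a config may override
_GEOMETRY_FIELDS = tuple(
    f.name for f in dataclasses.fields(GeometryParams) if f.name != "attachment_table"
)


def default_ligament_table() -> dict[str, dict]:
    """Config mirror of the ligament table: stiffness (N/mm), reference strain."""
    return {
        name: {"stiffness": k, "reference_strain": eps}
        for name, (k, eps) in _tissue.DEFAULT_LIGAMENT_TABLE.items()
    }


def default_muscle_table() -> dict[str, dict]:
    table = {name: {"preload": f0} for name, f0 in _tissue.DEFAULT_MUSCLE_PRELOADS.items()}
    table["vastus_intermedius"] = {
        "preload": _tissue.DEFAULT_INITIAL_QUAD_FORCE,
        "controllable": True,
    }
    return table


@dataclass
class ScenarioConfig:
    """Complete, file-serializable description of one squat scenario."""

    schema_version: int = SCHEMA_VERSION
    geometry: dict = field(default_factory=dict)  # overrides of GeometryParams scalars
    ligaments: dict = field(default_factory=default_ligament_table)
    muscles: dict = field(default_factory=default_muscle_table)
    n_steps: int = 30
    hip_drop_total: float = 150.0
    grf_lower: float = 50.0
    grf_upper: float = 55.0
    controller: dict = field(default_factory=dict)  # ControllerConfig overrides
    pcl_release_percent: float = 0.0
    mu_femorotibial: float = 0.05
    mu_patellofemoral: float = 0.02
    contact_spacing: float = 1.5
    flexion_cap: float = DEFAULT_FLEXION_CAP
    output_dir: str = "kneesquat_out"

    def validate(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {self.schema_version} (expected {SCHEMA_VERSION})")
        unknown = set(self.geometry) - set(_GEOMETRY_FIELDS)
        if unknown:
            raise ValueError(f"unknown geometry keys: {sorted(unknown)}")
        known_lig = set(_tissue.DEFAULT_LIGAMENT_TABLE)
        unknown = set(self.ligaments) - known_lig
        if unknown:
            raise ValueError(f"unknown ligament bundles: {sorted(unknown)}")
        if not 0.0 <= self.pcl_release_percent < 100.0:
            raise ValueError("pcl_release_percent must be in [0, 100)")
        if not 0 < self.grf_lower < self.grf_upper:
            raise ValueError("GRF band must satisfy 0 < lower < upper")
        GeometryParams(**self.geometry).validate()
        ControllerConfig(**self.controller)
        SquatSchedule(self.n_steps, self.hip_drop_total)

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    # -- model construction --------------------------------------------------

    def geometry_params(self) -> GeometryParams:
        return GeometryParams(**self.geometry)

    def build_model(self) -> KneeModel:
        self.validate()
        model = KneeModel.build_default(
            params=self.geometry_params(),
            release_percent=0.0,
            contact_spacing=self.contact_spacing,
            mu_femorotibial=self.mu_femorotibial,
            mu_patellofemoral=self.mu_patellofemoral,
        )
        # apply ligament table overrides, then re-calibrate and release
        from .geometry import pose_at_reference_flexion
        from .solver import REFERENCE_FLEXION_DEG

        changed = False
        for name, row in self.ligaments.items():
            b = model.bundles[name]
            if row.get("stiffness", b.stiffness) != b.stiffness or row.get(
                "reference_strain", b.reference_strain
            ) != b.reference_strain:
                model.bundles[name] = dataclasses.replace(
                    b,
                    stiffness=float(row.get("stiffness", b.stiffness)),
                    reference_strain=float(row.get("reference_strain", b.reference_strain)),
                )
                changed = True
        if changed:
            ref = pose_at_reference_flexion(REFERENCE_FLEXION_DEG, model.geometry.params)
            model.bundles = _tissue.calibrate_slack_lengths(model.bundles, ref)
        model.bundles = _tissue.apply_pcl_release(model.bundles, self.pcl_release_percent)
        for name, row in self.muscles.items():
            m = model.muscles[name]
            model.muscles[name] = dataclasses.replace(m, preload=float(row.get("preload", m.preload)))
        return model

    def schedule(self) -> SquatSchedule:
        return SquatSchedule(self.n_steps, self.hip_drop_total)

    def band(self) -> GrfBand:
        return GrfBand(self.grf_lower, self.grf_upper)

    def controller_config(self) -> ControllerConfig:
        kw = dict(self.controller)
        kw.setdefault("initial_quad_force", self.muscles.get("vastus_intermedius", {}).get("preload", 21.0))
        return ControllerConfig(**kw)


def run_scenario(config: ScenarioConfig) -> SquatTrace:
    """Run one force-controlled squat described by a scenario config."""
    model = config.build_model()
    return run_squat(
        model,
        schedule=config.schedule(),
        controller=config.controller_config(),
        band=config.band(),
        flexion_cap=config.flexion_cap,
    )


# ---------------------------------------------------------------------------
# release comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    """Cross-scenario descriptive statistics of a PCL-release comparison."""

    releases: list[float]
    per_scenario: dict  # release -> summary metrics
    orderings: dict  # cross-scenario checks (only when >= 2 scenarios)
    partial: dict  # release -> failure message for scenarios that aborted
    traces: dict = field(default_factory=dict, repr=False)  # release -> SquatTrace

    def to_json(self, path=None) -> str:
        payload = {
            "releases": self.releases,
            "per_scenario": self.per_scenario,
            "orderings": self.orderings,
            "partial": self.partial,
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=float)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def scenario_isolation_check(configs: dict) -> None:
    """Verify that release-comparison configs differ only in the release field."""
    items = list(configs.items())
    ref_release, ref_cfg = items[0]
    ref = asdict(ref_cfg)
    ref.pop("pcl_release_percent")
    for release, cfg in items[1:]:
        other = asdict(cfg)
        got_release = other.pop("pcl_release_percent")
        if got_release != release:
            raise ValueError(f"config for release {release} carries pcl_release_percent={got_release}")
        diff = {k for k in ref if ref[k] != other.get(k)}
        if diff:
            raise ValueError(f"scenarios differ beyond the PCL release: {sorted(diff)}")


def _anterior_excursion(ap: np.ndarray) -> float:
    """Posterior-to-anterior excursion: largest rise from a running minimum.

    This matches the squat-comparison metric: the tibia first drifts posterior
    and later comes anterior; the reported number is the travel from the
    posterior-most position to the subsequent anterior peak.
    """
    running_min = np.minimum.accumulate(ap)
    return float((ap - running_min).max())


def run_release_comparison(base: ScenarioConfig, releases=(0.0, 50.0, 75.0)) -> ComparisonReport:
    """Run the release scenarios under identical boundary conditions and compare.

    Returns per-scenario summaries plus cross-scenario orderings computed on
    the load steps present in all traces.  A scenario failing mid-squat is
    reported as partial; orderings use the common range only.
    """
    releases = [float(r) for r in releases]
    configs = {}
    for r in releases:
        cfg = dataclasses.replace(base, pcl_release_percent=r)
        cfg.ligaments = {k: dict(v) for k, v in base.ligaments.items()}
        cfg.muscles = {k: dict(v) for k, v in base.muscles.items()}
        cfg.geometry = dict(base.geometry)
        cfg.controller = dict(base.controller)
        configs[r] = cfg
    scenario_isolation_check(configs)

    traces: dict[float, SquatTrace] = {}
    partial: dict[float, str] = {}
    for r, cfg in configs.items():
        tr = run_scenario(cfg)
        traces[r] = tr
        if tr.failure:
            partial[r] = tr.failure

    frames = {r: tr.to_frame() for r, tr in traces.items()}
    per_scenario = {}
    for r, df in frames.items():
        if df.empty:
            per_scenario[r] = {"n_steps": 0}
            continue
        over40 = df[df.flexion_deg > 40.0]
        per_scenario[r] = {
            "n_steps": int(len(df)),
            "flexion_range_deg": [float(df.flexion_deg.min()), float(df.flexion_deg.max())],
            "grf_range_N": [float(df.grf_N.min()), float(df.grf_N.max())],
            "max_anterior_translation_mm": _anterior_excursion(df.ap_translation_mm.values),
            "peak_internal_rotation_deg": float(df.internal_rotation_deg.max()),
            "peak_inlay_stress_over40_MPa": float(over40.inlay_peak_stress_MPa.max()) if len(over40) else np.nan,
            "peak_inlay_stress_MPa": float(df.inlay_peak_stress_MPa.max()),
            "peak_patella_stress_MPa": float(df.patella_peak_stress_MPa.max()),
            "quad_force_final_N": float(df.quad_force_N.iloc[-1]),
        }

    orderings: dict = {}
    if len(releases) >= 2:
        n_common = min(len(df) for df in frames.values())
        if n_common >= 1:
            rel_sorted = sorted(releases)
            # orderings use the load steps present in all traces only
            ap = [
                _anterior_excursion(frames[r].ap_translation_mm.values[:n_common]) for r in rel_sorted
            ]
            stress = []
            for r in rel_sorted:
                df_c = frames[r].iloc[:n_common]
                over = df_c[df_c.flexion_deg > 40.0]
                stress.append(float(over.inlay_peak_stress_MPa.max()) if len(over) else np.nan)
            quad = {r: frames[r].quad_force_N.values[:n_common] for r in releases}
            pat = {r: frames[r].patella_peak_stress_MPa.values[:n_common] for r in releases}
            q0 = quad[rel_sorted[0]]
            p0 = pat[rel_sorted[0]]
            orderings = {
                "common_steps": int(n_common),
                "anterior_translation_mm": ap,
                "anterior_translation_decreasing": all(a > b for a, b in zip(ap, ap[1:])),
                "inlay_stress_over40_MPa": stress,
                "inlay_stress_over40_decreasing": all(
                    (a > b) or (np.isnan(a) or np.isnan(b)) for a, b in zip(stress, stress[1:])
                ),
                "max_quad_force_rel_diff": max(
                    float(np.max(np.abs(quad[r] - q0)) / np.max(np.abs(q0))) for r in rel_sorted[1:]
                ),
                "max_patella_stress_rel_diff": max(
                    float(np.max(np.abs(pat[r] - p0)) / np.max(np.abs(p0))) for r in rel_sorted[1:]
                ),
            }
            for name in ("LCL", "MCLa", "MCLd", "MCLo"):
                col = f"force_{name}_N"
                flex0 = frames[rel_sorted[0]].flexion_deg.values[:n_common]
                window = (flex0 > 40.0) & (flex0 < 62.0)
                if window.any():
                    means = [float(frames[r][col].values[:n_common][window].mean()) for r in rel_sorted]
                    orderings[f"{name}_midflexion_mean_N"] = means
    return ComparisonReport(releases=releases, per_scenario=per_scenario, orderings=orderings, partial=partial, traces=traces)


def write_comparison_outputs(report: ComparisonReport, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for r, tr in report.traces.items():
        tr.to_csv(outdir / f"trace_release_{int(r):02d}.csv")
    report.to_json(outdir / "comparison_report.json")


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

_RELEASE_LABELS = {0.0: "unreleased", 50.0: "50%", 75.0: "75%"}


def _setup_matplotlib():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "kneesquat"
    return plt


def _save(fig, path):
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)


def plot_trace(traces: dict, outdir, formats=("svg",)) -> list[str]:
    """Deterministic figures: AP translation, peak stresses and ligament forces
    versus flexion, one line per scenario.

    ``traces`` maps release percent -> SquatTrace (or DataFrame).  Returns the
    written file paths.  Figures carry no timestamps, so rerunning on the same
    trace reproduces identical files.
    """
    if not traces:
        raise ValueError("at least one trace required")
    plt = _setup_matplotlib()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = {}
    for r, tr in traces.items():
        df = tr.to_frame() if hasattr(tr, "to_frame") and not hasattr(tr, "columns") else tr
        if len(df) == 0:
            raise ValueError(f"trace for release {r} is empty")
        frames[float(r)] = df
    written = []

    def label(r):
        return _RELEASE_LABELS.get(r, f"{r:g}%")

    # AP translation vs flexion
    fig, ax = plt.subplots(figsize=(6, 4))
    for r, df in sorted(frames.items()):
        ax.plot(df.flexion_deg, df.ap_translation_mm, marker="o", markersize=2.5, label=label(r))
    ax.set_xlabel("flexion (deg)")
    ax.set_ylabel("AP tibial translation (mm, anterior +)")
    ax.legend()
    fig.tight_layout()
    for ext in formats:
        p = outdir / f"ap_translation.{ext}"
        _save(fig, p)
        written.append(str(p))
    plt.close(fig)

    # peak stresses vs flexion (inlay top, patella bottom)
    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    for r, df in sorted(frames.items()):
        axes[0].plot(df.flexion_deg, df.inlay_peak_stress_MPa, label=label(r))
        axes[1].plot(df.flexion_deg, df.patella_peak_stress_MPa, label=label(r))
    axes[0].set_ylabel("inlay peak stress (MPa)")
    axes[1].set_ylabel("patella peak stress (MPa)")
    axes[1].set_xlabel("flexion (deg)")
    axes[0].legend()
    fig.tight_layout()
    for ext in formats:
        p = outdir / f"peak_stress.{ext}"
        _save(fig, p)
        written.append(str(p))
    plt.close(fig)

    # ligament forces vs flexion
    bundles = ["LCL", "MCLa", "MCLo", "MCLd", "PCLa", "PCLp"]
    fig, axes = plt.subplots(3, 2, sharex=True, figsize=(8, 8))
    for ax, name in zip(axes.ravel(), bundles):
        for r, df in sorted(frames.items()):
            ax.plot(df.flexion_deg, df[f"force_{name}_N"], label=label(r))
        ax.set_title(name)
        ax.set_ylabel("force (N)")
    for ax in axes[-1]:
        ax.set_xlabel("flexion (deg)")
    axes[0, 0].legend()
    fig.tight_layout()
    for ext in formats:
        p = outdir / f"ligament_forces.{ext}"
        _save(fig, p)
        written.append(str(p))
    plt.close(fig)
    return written
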