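"""End-to-end orchestration: generate → histogram → WHAM → baseline →
features → thermodynamic fits over the full (T × IS) grid.

Each temperature is solved by WHAM independently at its own k_BT, matching
per-temperature umbrella studies; there is no multi-temperature reweighting.
Partial failures (an unconverged WHAM, a profile without a contact minimum)
are recorded per grid cell without aborting the rest of the grid.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import __version__
from .features import PMFFeatures, find_extrema
from .model import Condition, ModelPotential, WindowSpec
from .sampling import (
    ReactionCoordinateSeries,
    StudyDataset,
    StudyProtocol,
    adamantane_like_protocol,
    generate_study,
    hexane_like_protocol,
)
from .seriesio import (
    read_series_file,
    series_filename,
    write_features_table,
    write_pmf_table,
    write_series_file,
    write_thermo_table,
)
from .thermo import (
    IonicFit,
    ThermoFit,
    ThermoState,
    fit_free_energy_vs_ionic_strength,
    fit_free_energy_vs_temperature,
    thermo_state,
)
from .wham import bootstrap_pmf_uncertainty, build_histograms, subtract_baseline, wham_solve

__all__ = ["PipelineSettings", "StudyReport", "protocol_from_config", "run_pipeline"]

log = logging.getLogger("hydrotherm")


@dataclass(frozen=True)
class PipelineSettings:
    """Analysis-stage knobs (WHAM grid, bootstrap, feature scan, thermo)."""

    bin_width: float = 0.1
    hist_range: Optional[Tuple[float, float]] = None
    tol: float = 1e-7
    max_iter: int = 100_000
    n_boot: int = 20
    block_len: int = 200
    smooth_window: int = 3
    min_prominence: float = 0.05
    eval_T: float = 298.0


@dataclass
class StudyReport:
    """All pipeline products for one study, plus provenance."""

    protocol: StudyProtocol
    settings: PipelineSettings
    pmfs: Dict[Tuple[float, float], "object"] = field(default_factory=dict)
    features: Dict[Tuple[float, float], PMFFeatures] = field(default_factory=dict)
    feature_errors: Dict[Tuple[float, float], float] = field(default_factory=dict)
    thermo_fits: Dict[float, ThermoFit] = field(default_factory=dict)
    thermo_states: Dict[float, ThermoState] = field(default_factory=dict)
    ionic_fits: Dict[float, IonicFit] = field(default_factory=dict)
    failures: Dict[Tuple[float, float], str] = field(default_factory=dict)
    notes: List[str] = field(default_factory=list)
    provenance: Dict[str, object] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures

    def feature_rows(self) -> List[dict]:
        rows = []
        for (T, IS), f in sorted(self.features.items(), key=lambda kv: (kv[0][1], kv[0][0])):
            rows.append(
                dict(
                    T_K=T,
                    IS_M=IS,
                    cm_pos=f.cm_pos,
                    cm_depth=f.cm_depth,
                    cm_depth_err=self.feature_errors.get((T, IS), np.nan),
                    dm_pos=f.dm_pos,
                    dm_height=f.dm_height,
                    ssm_pos=f.ssm_pos,
                    ssm_depth=f.ssm_depth,
                )
            )
        return rows

    def thermo_rows(self) -> List[dict]:
        rows = []
        for IS in sorted(self.thermo_fits):
            fit = self.thermo_fits[IS]
            st = self.thermo_states[IS]
            rows.append(
                dict(
                    IS_M=IS,
                    a=fit.a,
                    b=fit.b,
                    c=fit.c,
                    dF=st.dF,
                    dU=st.dU,
                    dS=st.dS,
                    dCv=st.dCv,
                    dF_err=st.dF_err,
                    dU_err=st.dU_err,
                    dS_err=st.dS_err,
                    dCv_err=st.dCv_err,
                    eval_T=st.T,
                )
            )
        return rows


def protocol_from_config(config: dict) -> Tuple[StudyProtocol, PipelineSettings]:
    """Build a protocol and analysis settings from a configuration mapping.

    A ``preset`` key (``hexane`` / ``adamantane``) supplies defaults which
    the ``model``, ``ladder``, ``conditions`` and ``sampler`` sections may
    override; ``wham``, ``features`` and ``thermo`` configure the analysis.
    """
    config = dict(config or {})
    preset = config.get("preset", "hexane")
    if preset in ("hexane", "hexane_like"):
        proto = hexane_like_protocol()
    elif preset in ("adamantane", "adamantane_like"):
        proto = adamantane_like_protocol()
    else:
        raise ValueError(f"unknown preset {preset!r}")

    overrides: Dict[str, object] = {}
    model_cfg = config.get("model")
    if model_cfg:
        base = proto.model
        kwargs = {k: v for k, v in model_cfg.items()}
        if "depth_T_quad" in kwargs:
            kwargs["depth_T_quad"] = tuple(float(v) for v in kwargs["depth_T_quad"])
        from dataclasses import asdict

        merged = {**asdict(base), **kwargs}
        overrides["model"] = ModelPotential(**merged)
    ladder_cfg = config.get("ladder")
    if ladder_cfg:
        k = float(ladder_cfg.get("k", 2.0))
        overrides["ladder"] = tuple(
            WindowSpec(d0=float(d), k=k, label=f"w{i + 1:02d}")
            for i, d in enumerate(ladder_cfg["d0"])
        )
    cond_cfg = config.get("conditions", {})
    if "temperatures" in cond_cfg:
        overrides["temperatures"] = tuple(float(t) for t in cond_cfg["temperatures"])
    if "ionic_strengths" in cond_cfg:
        overrides["ionic_strengths"] = tuple(float(i) for i in cond_cfg["ionic_strengths"])
    if "n_samples" in cond_cfg:
        overrides["n_samples"] = int(cond_cfg["n_samples"])
    samp_cfg = config.get("sampler", {})
    for key in ("n_chains", "thin"):
        if key in samp_cfg:
            overrides[key] = int(samp_cfg[key])
    if "bias_convention" in samp_cfg:
        overrides["bias_convention"] = samp_cfg["bias_convention"]
    wham_cfg = config.get("wham", {})
    if "baseline_range" in wham_cfg:
        overrides["baseline_range"] = tuple(float(v) for v in wham_cfg["baseline_range"])

    from dataclasses import replace

    proto = replace(proto, **overrides)

    feat_cfg = config.get("features", {})
    thermo_cfg = config.get("thermo", {})
    settings = PipelineSettings(
        bin_width=float(wham_cfg.get("bin_width", 0.1)),
        hist_range=tuple(wham_cfg["range"]) if "range" in wham_cfg else None,
        tol=float(wham_cfg.get("tol", 1e-7)),
        max_iter=int(wham_cfg.get("max_iter", 100_000)),
        n_boot=int(wham_cfg.get("n_boot", 20)),
        block_len=int(wham_cfg.get("block_len", 200)),
        smooth_window=int(feat_cfg.get("smooth_window", 3)),
        min_prominence=float(feat_cfg.get("min_prominence", 0.05)),
        eval_T=float(thermo_cfg.get("eval_T", 298.0)),
    )
    return proto, settings


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_series_from_files(
    protocol: StudyProtocol, series_dir: str
) -> Tuple[Dict[Tuple[str, float, float], ReactionCoordinateSeries], Dict]:
    series = {}
    failures = {}
    for cond in protocol.conditions:
        for w in protocol.ladder:
            path = os.path.join(series_dir, series_filename(w, cond))
            key = (w.label, cond.T, cond.IS)
            if not os.path.exists(path):
                failures[(cond.T, cond.IS)] = f"missing series file {path}"
                continue
            series[key] = read_series_file(path)
    return series, failures


def run_pipeline(
    config: dict,
    seed: int,
    mode: str = "synthetic",
    series_dir: Optional[str] = None,
    out_dir: Optional[str] = None,
    dataset: Optional[StudyDataset] = None,
) -> StudyReport:
    """Run every stage over the full grid and assemble a report.

    ``mode`` is ``"synthetic"`` (sample the model potential) or
    ``"from-files"`` (read series from ``series_dir``).  A pre-generated
    ``dataset`` may be supplied to skip regeneration.  With ``out_dir`` the
    TSV tables and per-condition PMF profiles are written there.
    """
    protocol, settings = protocol_from_config(config)
    report = StudyReport(protocol=protocol, settings=settings)
    report.provenance = dict(
        config_hash=_config_hash(config),
        seed=int(seed),
        version=__version__,
        mode=mode,
    )

    if mode == "synthetic":
        if dataset is None:
            dataset = generate_study(protocol, seed)
        all_series = dataset.series
    elif mode == "from-files":
        if not series_dir:
            raise ValueError("from-files mode requires series_dir")
        all_series, missing = _load_series_from_files(protocol, series_dir)
        report.failures.update(missing)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.SeedSequence(seed ^ 0x5EED)
    boot_seeds = {
        (c.T, c.IS): int(s.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        for c, s in zip(protocol.conditions, rng.spawn(len(protocol.conditions)))
    }

    for cond in protocol.conditions:
        cell = (cond.T, cond.IS)
        if cell in report.failures:
            continue
        cell_series = [
            all_series[(w.label, cond.T, cond.IS)]
            for w in protocol.ladder
            if (w.label, cond.T, cond.IS) in all_series
        ]
        if not cell_series:
            report.failures[cell] = "no series available"
            continue
        try:
            hist = build_histograms(
                cell_series,
                bin_width=settings.bin_width,
                hist_range=settings.hist_range,
                bias_convention=protocol.bias_convention,
            )
            pmf = wham_solve(hist, tol=settings.tol, max_iter=settings.max_iter)
            pmf = subtract_baseline(pmf, protocol.baseline_range)
            if settings.n_boot >= 2:
                pmf.F_err = bootstrap_pmf_uncertainty(
                    cell_series,
                    bin_width=settings.bin_width,
                    hist_range=settings.hist_range,
                    baseline_range=protocol.baseline_range,
                    n_boot=settings.n_boot,
                    block_len=settings.block_len,
                    seed=boot_seeds[cell],
                    tol=settings.tol,
                    max_iter=settings.max_iter,
                    bias_convention=protocol.bias_convention,
                )
            feats = find_extrema(
                pmf,
                smooth_window=settings.smooth_window,
                min_prominence=settings.min_prominence,
            )
            report.pmfs[cell] = pmf
            report.features[cell] = feats
            if pmf.F_err is not None:
                cm_bin = int(np.argmin(np.abs(pmf.bin_centers - feats.cm_pos)))
                report.feature_errors[cell] = float(pmf.F_err[cm_bin])
            log.info(
                "cell T=%g IS=%g: WHAM %s in %d iters, CM %.2f Å / %.3f kcal/mol",
                cond.T, cond.IS, "converged" if pmf.converged else "NOT converged",
                pmf.n_iter, feats.cm_pos, feats.cm_depth,
            )
        except (ValueError, RuntimeError) as exc:
            report.failures[cell] = str(exc)
            log.warning("cell T=%g IS=%g failed: %s", cond.T, cond.IS, exc)

    # thermo stage: per-IS quadratic fit over temperature
    if len(protocol.temperatures) < 3:
        report.notes.append(
            "insufficient temperatures for the quadratic thermo fit (need >= 3); "
            "thermo stage skipped"
        )
    else:
        for IS in protocol.ionic_strengths:
            pts = []
            for T in protocol.temperatures:
                if (T, IS) not in report.features:
                    continue
                f = report.features[(T, IS)]
                err = report.feature_errors.get((T, IS))
                if err is not None and np.isfinite(err) and err > 0:
                    pts.append((T, f.cm_depth, err))
                else:
                    pts.append((T, f.cm_depth))
            if len(pts) < 3:
                report.notes.append(f"IS={IS}: fewer than 3 usable temperatures")
                continue
            if not all(len(p) == 3 for p in pts):
                pts = [(p[0], p[1]) for p in pts]
            fit = fit_free_energy_vs_temperature(pts, condition_IS=IS)
            report.thermo_fits[IS] = fit
            report.thermo_states[IS] = thermo_state(fit, settings.eval_T)

    # ionic stage: per-T linear fit over ionic strength
    if len(protocol.ionic_strengths) >= 2:
        for T in protocol.temperatures:
            pts = []
            for IS in protocol.ionic_strengths:
                if (T, IS) not in report.features:
                    continue
                f = report.features[(T, IS)]
                err = report.feature_errors.get((T, IS))
                if err is not None and np.isfinite(err) and err > 0:
                    pts.append((IS, f.cm_depth, err))
                else:
                    pts.append((IS, f.cm_depth))
            if len(pts) < 2:
                continue
            if not all(len(p) == 3 for p in pts):
                pts = [(p[0], p[1]) for p in pts]
            report.ionic_fits[T] = fit_free_energy_vs_ionic_strength(pts, T=T)
    else:
        report.notes.append("single ionic strength: ionic-strength fit skipped")

    if out_dir:
        _write_outputs(report, out_dir)
    return report


def _write_outputs(report: StudyReport, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    write_features_table(report.feature_rows(), os.path.join(out_dir, "features.tsv"))
    if report.thermo_rows():
        write_thermo_table(report.thermo_rows(), os.path.join(out_dir, "thermo.tsv"))
    ionic_rows = [
        dict(
            T_K=T,
            slope=f.slope,
            intercept=f.intercept,
            slope_err=float(np.sqrt(f.cov[1, 1])) if np.isfinite(f.cov[1, 1]) else np.nan,
        )
        for T, f in sorted(report.ionic_fits.items())
    ]
    if ionic_rows:
        write_thermo_table(ionic_rows, os.path.join(out_dir, "ionic_fits.tsv"))
    for (T, IS), pmf in report.pmfs.items():
        write_pmf_table(pmf, os.path.join(out_dir, f"pmf_T{T:g}_IS{IS:g}.tsv"))
    if report.notes or report.failures:
        with open(os.path.join(out_dir, "run_log.txt"), "w") as fh:
            for n in report.notes:
                fh.write(f"NOTE: {n}\n")
            for cell, msg in sorted(report.failures.items()):
                fh.write(f"FAILED T={cell[0]} IS={cell[1]}: {msg}\n")
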