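"""End-to-end workflow: structure -> segments -> pool -> profiles -> fits.

Stages, in order: baseline assessment of the unmodified predicted structure
against the experimental I(q) (optimal scale + chi^2) and P(r); Monte Carlo
pool generation over the flexible segments; stride sub-selection with an
Rg-distribution representativeness check; per-conformer P(r) and I(q)
profiles; NNLS fits with the experimental P(r) as target (without and with
error weighting) and with I(q) as target; and a final refit of the union of
all selected conformers (plus the starting structure) against I(q).  Every
random stage records its seed in the run report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ensemble, model_io, sampling, sasdata, scattering
from .model_io import ProteinModel, SegmentSpec

log = logging.getLogger("saxsensemble")


@dataclass
class RunConfig:
    structure_path: str | None = None
    data_path: str | None = None
    pr_path: str | None = None           # GNOM-style .out; else IFT of data
    segments: list[tuple[int, int]] | None = None
    confidence_threshold: float = 60.0
    min_segment_length: int = 5
    n_trials: int = 2000
    max_step_deg: float = 30.0
    stride: int = 5
    seed: int = 0
    dmax: float | str = "auto"
    ift_alpha: float | None = None
    fit_pr: bool = True
    fit_iq: bool = True
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.segments is not None:
            cfg.segments = [tuple(s) for s in cfg.segments]
        return cfg


@dataclass
class RunReport:
    """Full record of one pipeline run (the Table-2-style row schema)."""

    label: str
    seed: int
    segments: list[tuple[int, int]]
    baseline_chi2: float
    baseline_rg: float
    pool_size: int
    pool_subselected: int
    acceptance_fraction: float
    rg_hist_max_difference: float
    fits: dict = field(default_factory=dict)     # name -> EnsembleFitResult.to_dict()
    quality: dict | None = None
    dmax_target: float | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label, "seed": self.seed,
            "segments": [list(s) for s in self.segments],
            "baseline_chi2": self.baseline_chi2,
            "baseline_rg": self.baseline_rg,
            "pool_size": self.pool_size,
            "pool_subselected": self.pool_subselected,
            "acceptance_fraction": self.acceptance_fraction,
            "rg_hist_max_difference": self.rg_hist_max_difference,
            "dmax_target": self.dmax_target,
            "quality": self.quality,
            "fits": self.fits,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [f"run {self.label!r} (seed {self.seed})",
                 f"  baseline chi^2 {self.baseline_chi2:.3f}, Rg {self.baseline_rg:.2f} Å",
                 f"  pool {self.pool_size} accepted -> {self.pool_subselected} "
                 f"representatives (acceptance {100 * self.acceptance_fraction:.0f}%)"]
        for name, f in self.fits.items():
            rg = f.get("rg_rms")
            lines.append(
                f"  {name}: chi^2 {f['chi2']:.3f}, {len(f['member_ids'])} members"
                + (f", <Rg> {rg:.2f} Å" if rg is not None else ""))
        return "\n".join(lines)


def _pr_column(model: ProteinModel, r_values: np.ndarray) -> scattering.DistanceDistribution:
    """Computed P(r) interpolated onto the experimental r grid."""
    pr = scattering.compute_pr(model, bin_width=1.0)
    p = np.interp(r_values, pr.r_grid, pr.p, left=0.0, right=0.0)
    return scattering.DistanceDistribution(r_grid=r_values, p=p, dmax=pr.dmax)


def run_pipeline(config: RunConfig, model: ProteinModel | None = None,
                 data: scattering.IntensityProfile | None = None,
                 pr_target: scattering.DistanceDistribution | None = None) -> RunReport:
    """Execute the full workflow; in-memory objects may replace file paths."""
    # --- inputs
    if model is None:
        if config.structure_path is None:
            raise ValueError("no structure given")
        model = model_io.read_model(config.structure_path)
    if model.b is None:
        model = model_io.assign_scattering_factors(model)
    if data is None:
        if config.data_path is None:
            raise ValueError("no intensity data given")
        data = sasdata.read_iq(config.data_path)
    if pr_target is None and config.pr_path:
        pr_target, _, _ = sasdata.read_gnom_out(config.pr_path)
        pr_target = sasdata.rebin_pr(pr_target, 1.0)
    dmax_used = None
    if pr_target is None and config.fit_pr:
        if config.dmax == "auto":
            dmax_used, _diag = sasdata.select_dmax(data, alpha=config.ift_alpha)
        else:
            dmax_used = float(config.dmax)
        ift_res = sasdata.ift(data, dmax=dmax_used, alpha=config.ift_alpha)
        pr_target = ift_res.pr
        log.info("IFT target: %s", ift_res.summary())
    if pr_target is not None and pr_target.errors is None:
        # propagate a flat 2% of peak as nominal errors for weighted fits
        pr_target.errors = np.full_like(pr_target.p, 0.02 * max(pr_target.p.max(), 1e-30))

    # --- baseline assessment of the unmodified structure
    base_iq = scattering.debye_iq(model, data.q_grid)
    scale, baseline_chi2, _resid = ensemble.scale_and_chi2(base_iq, data)
    baseline_rg = scattering.rg_from_model(model)
    guinier = None
    try:
        guinier = sasdata.guinier_fit(data, max_qrg=1.3)
    except ValueError:
        pass
    quality = sasdata.data_quality(
        data, rg_hint=guinier.rg if guinier else baseline_rg).to_dict()
    log.info("baseline chi^2 %.3f (scale %.3g), model Rg %.2f", baseline_chi2,
             scale, baseline_rg)

    # --- segments
    if config.segments:
        segments = SegmentSpec(ranges=list(config.segments))
    else:
        segments = model_io.suggest_flexible_segments(
            model, config.confidence_threshold, config.min_segment_length)
    if len(segments) == 0:
        log.info("no flexible segments: baseline assessment only")
        return RunReport(label=model.label, seed=config.seed,
                         segments=[], baseline_chi2=baseline_chi2,
                         baseline_rg=baseline_rg, pool_size=0,
                         pool_subselected=0, acceptance_fraction=0.0,
                         rg_hist_max_difference=0.0, quality=quality,
                         dmax_target=dmax_used)

    # --- pool generation and sub-selection
    pool = sampling.sample_pool(model, segments, n_trials=config.n_trials,
                                max_step_deg=config.max_step_deg,
                                seed=config.seed)
    sub = sampling.subselect_pool(pool, config.stride)
    _, _, hist_diff = sampling.compare_rg_distributions(pool, sub)
    log.info("pool %d accepted / %d trials; %d representatives (stride %d), "
             "Rg-hist max diff %.3g", pool.n_accepted, pool.n_trials,
             len(sub), config.stride, hist_diff)

    # --- per-conformer profiles
    member_rg = np.array(sub.rg_values)
    pr_columns, member_dmax, iq_columns = [], [], []
    for m in sub.models:
        if config.fit_pr and pr_target is not None:
            col = _pr_column(m, pr_target.r_grid)
            pr_columns.append(col)
            member_dmax.append(col.dmax)
        else:
            member_dmax.append(scattering.compute_pr(m).dmax)
        iq_columns.append(scattering.debye_iq(m, data.q_grid))
    member_dmax = np.array(member_dmax)

    fits: dict[str, ensemble.EnsembleFitResult] = {}
    if config.fit_pr and pr_target is not None:
        for weighted, name in ((False, "pr_unweighted"), (True, "pr_weighted")):
            res = ensemble.fit_ensemble(
                pr_columns, pr_target, error_weighted=weighted,
                member_rg=member_rg, member_dmax=member_dmax)
            # score the real-space ensemble against the measured I(q): the
            # composite intensity of the selected members, scaled to the data
            combo_iq = ensemble.composite_profile(
                [iq_columns[i] for i in res.member_ids], res.fractions)
            res.scale, res.chi2, res.weighted_residuals = \
                ensemble.scale_and_chi2(combo_iq, data)
            fits[name] = res
            log.info("%s: %s", name, res.to_dict())
    if config.fit_iq:
        fits["iq"] = ensemble.fit_ensemble(
            iq_columns, data, member_rg=member_rg, member_dmax=member_dmax)
        log.info("iq fit: %s", fits["iq"].to_dict())

    # --- union refit (selected members + the starting structure) against I(q)
    if fits:
        base_dmax = scattering.compute_pr(model).dmax
        fits["union"] = ensemble.refit_union(
            list(fits.values()), iq_columns, data,
            extra_profiles=[base_iq], extra_ids=[-1],
            member_rg=member_rg, member_dmax=member_dmax,
            extra_rg=[baseline_rg], extra_dmax=[base_dmax])
        log.info("union refit: %s", fits["union"].to_dict())

    report = RunReport(
        label=model.label, seed=config.seed, segments=segments.ranges,
        baseline_chi2=baseline_chi2, baseline_rg=baseline_rg,
        pool_size=pool.n_accepted, pool_subselected=len(sub),
        acceptance_fraction=pool.n_accepted / max(pool.n_trials, 1),
        rg_hist_max_difference=hist_diff,
        fits={k: v.to_dict() for k, v in fits.items()},
        quality=quality, dmax_target=dmax_used)

    # --- artifacts
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        pool.write_manifest(out / "pool_manifest.json")
        if "union" in fits:
            selected = [sub.models[i] for i in fits["union"].member_ids if i >= 0]
            if selected:
                model_io.write_pool(selected, out / "selected_conformers.pdb")
        for name, res in fits.items():
            res.to_json(out / f"fit_{name}.json")
            if res.weighted_residuals is not None and res.target_kind == "iq":
                np.savetxt(out / f"residuals_{name}.tsv",
                           np.column_stack([data.q_grid, res.weighted_residuals]),
                           header="q weighted_residual")
    return report
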