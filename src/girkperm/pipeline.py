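"""End-to-end pipeline runners tying readers, generators and analyses together.

A run takes a resolved :class:`PipelineConfig`, executes its stages, and
writes a reproducible report bundle (CSV + JSON, plus an echo of the
resolved configuration) into the output directory.  Every output bundle is
reproducible from its echoed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from girkperm import ephys, fma, geometry, permeation
from girkperm.errors import DataError, GirkpermError
from girkperm.trajectory import Trajectory, read_toy_trajectory, select

__all__ = ["PipelineConfig", "run_md_pipeline", "run_ephys_pipeline"]

log = logging.getLogger("girkperm")


@dataclass
class PipelineConfig:
    """Resolved configuration; serialised into every output bundle."""

    sf_residues: tuple[int, ...] = (154, 155, 156, 157, 158)
    cylinder_radius: float = 5.0
    entry_margin: float = 1.0
    exit_margin: float = 1.0
    min_block_dwell: float = 50.0  # ns
    occupancy_bin_width: float = 0.25  # Å
    hbond_max_ha: float = 2.5
    hbond_max_da: float = 3.5
    hbond_min_angle: float = 120.0
    fma_n_components: int = 50
    fma_exclude_residues: tuple[tuple[int, int], ...] = ()
    fma_build_ns: tuple[float, float] = (0.0, 2500.0)
    fma_validate_ns: tuple[float, float] = (2500.0, 9000.0)
    decade_slope: float = ephys.DECADE_SLOPE_MV
    seed: int = 0
    outdir: str = "girkperm_out"

    def sf_definition(self) -> permeation.SFDefinition:
        return permeation.SFDefinition(
            residue_indices=tuple(self.sf_residues),
            cylinder_radius=self.cylinder_radius,
            entry_margin=self.entry_margin,
            exit_margin=self.exit_margin,
        )

    def echo(self, outdir: Path) -> None:
        (outdir / "girkperm_config.json").write_text(json.dumps(asdict(self), indent=2, default=list))


def _events_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ion_id": e.ion_id,
                "species": e.species,
                "direction": e.direction,
                "t_enter_ns": e.t_enter,
                "t_exit_ns": e.t_exit,
                "visited_sites": ">".join(e.visited_sites),
            }
            for e in events
        ],
        columns=["ion_id", "species", "direction", "t_enter_ns", "t_exit_ns", "visited_sites"],
    )


def run_md_pipeline(
    config: PipelineConfig,
    trajectory_paths: list[str],
    functional_csv: str | None = None,
) -> dict:
    """Permeation → occupancy → geometry (→ FMA) over one or more trajectories.

    Each path is a toy-format trajectory; events are pooled across runs for
    the summary rates and p_Na/p_K, with per-run rates retained (run-to-run
    heterogeneity is itself an observable).  If ``functional_csv`` (columns
    frame, value) is given, an FMA of the first trajectory is run with the
    configured basis size and split.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sf = config.sf_definition()

    all_events = []
    per_run = []
    total_time_us = 0.0
    trajectories: list[Trajectory] = []
    for path in trajectory_paths:
        if not Path(path).exists():
            raise DataError(f"trajectory file not found: {path}")
        log.info("permeation stage: %s", path)
        traj = read_toy_trajectory(path)
        trajectories.append(traj)
        span_us = (traj.times[-1] - traj.times[0]) / 1000.0
        total_time_us += span_us
        events = permeation.detect_permeation_events(traj, sf)
        all_events.extend(events)
        per_run.append(
            {
                "path": str(path),
                "time_us": span_us,
                "n_outward_K": sum(1 for e in events if e.species == "K" and e.direction == "outward"),
                "n_outward_Na": sum(1 for e in events if e.species == "Na" and e.direction == "outward"),
            }
        )
    _events_frame(all_events).to_csv(outdir / "events.csv", index=False)

    occ = permeation.occupancy_profile(trajectories[0], sf, z_bin_width=config.occupancy_bin_width)
    pd.DataFrame(
        {
            "z_center_A": occ.z_bin_centers,
            "density_K": occ.density.get("K", np.zeros_like(occ.z_bin_centers)),
            "density_Na": occ.density.get("Na", np.zeros_like(occ.z_bin_centers)),
        }
    ).to_csv(outdir / "occupancy.csv", index=False)

    log.info("geometry stage")
    mid_res = config.sf_residues[1]
    geom_rows = []
    try:
        series = geometry.opposing_ca_distance(trajectories[0], mid_res)
        geom_rows += [
            {"frame": i, "label": series.label, "value": v, "units": series.units}
            for i, v in enumerate(series.values)
        ]
    except GirkpermError as exc:  # geometry is best-effort on non-tetramer toys
        log.warning("geometry stage skipped: %s", exc)
    pd.DataFrame(geom_rows, columns=["frame", "label", "value", "units"]).to_csv(
        outdir / "geom.csv", index=False
    )

    summary = {
        "total_time_us": total_time_us,
        "rate_K_per_us": permeation.permeation_rate(all_events, total_time_us, "K"),
        "rate_Na_per_us": permeation.permeation_rate(all_events, total_time_us, "Na"),
        "per_run": per_run,
        "seed": config.seed,
    }
    n_k = sum(1 for e in all_events if e.species == "K" and e.direction == "outward")
    n_na = sum(1 for e in all_events if e.species == "Na" and e.direction == "outward")
    if n_k > 0:
        ratio = permeation.permeability_ratio_from_counts(n_na, n_k)
        summary["p_na_over_p_k"] = ratio.p_na_over_p_k
        summary["p_k_over_p_na"] = ratio.p_k_over_p_na

    if functional_csv is not None:
        log.info("FMA stage")
        traj = trajectories[0]
        f = pd.read_csv(functional_csv)["value"].to_numpy()
        sel = select(traj, "name CA")
        if len(sel) == 0:
            sel = select(traj, "all")
        basis = fma.pca_backbone(
            traj, sel, n_components=config.fma_n_components,
            exclude_residue_ranges=config.fma_exclude_residues,
        )
        b = fma.time_range_to_frames(traj, *config.fma_build_ns)
        v = fma.time_range_to_frames(traj, *config.fma_validate_ns)
        mode = fma.fma_build(basis, traj, f, b)
        r_val, mi_val = fma.fma_cross_validate(mode, traj, f, v)
        weights = fma.project_mode_on_structure(mode)
        pd.DataFrame({"atom_id": basis.atom_ids, "weight": weights}).to_csv(
            outdir / "mode_weights.csv", index=False
        )
        (outdir / "mode.json").write_text(
            json.dumps(
                {
                    "n_components": basis.n_components,
                    "coefficients": mode.coefficients.tolist(),
                    "intercept": mode.intercept,
                    "build_range_frames": list(mode.build_range),
                    "validation_range_frames": list(mode.validation_range),
                    "r_build": mode.r_build,
                    "r_validation": r_val,
                    "mi_validation_nats": mi_val,
                },
                indent=2,
            )
        )
        summary["fma_r_validation"] = r_val
        summary["fma_mi_validation_nats"] = mi_val

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    config.echo(outdir)
    return summary


def run_ephys_pipeline(
    config: PipelineConfig,
    iv_files: list[tuple[str, float, float]] | None = None,
    dose_files: list[str] | None = None,
) -> dict:
    """Reversal potentials, F_ir, GHK permeability ratios and Hill fits.

    ``iv_files`` lists (csv path, [K]_o mM, [Na]_o mM); each CSV has
    columns voltage_mV, current_nA.  GHK ratios are computed for every
    pair of solutions with distinct composition.  ``dose_files`` are CSVs
    with columns conc_uM, inhibition_pct.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"solutions": [], "ghk_pairs": [], "hill_fits": []}

    curves = []
    for path, k_o, na_o in iv_files or []:
        df = pd.read_csv(path)
        if df.empty:
            raise DataError(f"empty I-V table: {path}")
        iv = ephys.IVCurve(
            voltage=df["voltage_mV"].to_numpy(),
            current=df["current_nA"].to_numpy(),
            solution=(k_o, na_o),
            label=str(path),
        )
        v_rev = ephys.reversal_potential(iv)
        rec = {"path": str(path), "K_o_mM": k_o, "Na_o_mM": na_o, "v_rev_mV": v_rev}
        try:
            rec["f_ir"] = ephys.rectification_index(iv, v_rev)
        except DataError:
            rec["f_ir"] = None
        curves.append((iv, v_rev))
        results["solutions"].append(rec)

    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            (iv1, v1), (iv2, v2) = curves[i], curves[j]
            if iv1.solution == iv2.solution:
                continue
            pair = ephys.SolutionPair(
                K_o_1=iv1.solution[0], Na_o_1=iv1.solution[1],
                K_o_2=iv2.solution[0], Na_o_2=iv2.solution[1],
                v_rev_1=v1, v_rev_2=v2, decade_slope=config.decade_slope,
            )
            results["ghk_pairs"].append(
                {
                    "solution_1": iv1.label,
                    "solution_2": iv2.label,
                    "p_na_over_p_k": ephys.permeability_ratio_from_vrev(pair),
                }
            )

    for path in dose_files or []:
        df = pd.read_csv(path)
        if df.empty:
            raise DataError(f"empty dose-response table: {path}")
        dr = ephys.DoseResponse(
            concentration=df["conc_uM"].to_numpy(),
            inhibition=df["inhibition_pct"].to_numpy(),
            label=str(path),
        )
        fit = ephys.hill_fit(dr)
        results["hill_fits"].append(
            {"path": str(path), "ic50_uM": fit.ic50, "hill_slope": fit.h, "rmsd_pct": fit.rmsd}
        )

    (outdir / "ephys_results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    config.echo(outdir)
    return results
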