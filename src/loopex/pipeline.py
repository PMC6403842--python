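"""End-to-end drivers for the three loop-extrusion experiments.

Each driver builds its synthetic starting system, runs Langevin dynamics
interleaved with extruder updates, samples topology/geometry metrics, and
returns a :class:`RunRecord` that is exactly reproducible from the
configuration (every random stream derives from ``cfg.seed``):

* :func:`run_single_tad` - a knotted 133-bead TAD ring is unknotted by a
  cohesin handcuff pushing the knot into the CTCF/Top2B border;
* :func:`run_three_tad`  - a 400-bead three-TAD circle carrying a
  delocalised trefoil, extruded concurrently (or TAD by TAD);
* :func:`run_melt_demix` - the 8-ring confined melt: topological
  equilibration, simultaneous simple extrusion in every ring, and the
  Voronoi interfacial-area (demixing) series.

The final topology in ``outcome`` is always recomputed from the final
frame's coordinates alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .configs import (
    ExperimentConfig,
    equilibrated_melt,
    melt_topology_report,
    single_tad_ring,
    three_tad_circle,
)
from .demixing import interchain_area, tessellate
from .extrusion import (
    advance_walk,
    extrusion_progress,
    load_handcuff,
    load_simple_extruder,
    step_simple_extrusion,
)
from .model import ChainSystem, ForceField, IntegratorParams, logger, step_langevin, write_xyz
from .topology import identify_knot

__all__ = ["RunRecord", "run_single_tad", "run_three_tad", "run_melt_demix", "run_experiment"]

WALL_PAD = 0.5  # tessellation container: sphere radius + soft-wall penetration


@dataclass
class RunRecord:
    """Everything one experiment produced."""

    config: ExperimentConfig
    frames: list  # (step, positions copy)
    metrics: pd.DataFrame
    outcome: dict
    system: ChainSystem

    def save(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "trajectory.xyz", "w") as fh:
            snap = self.system.copy()
            for step, pos in self.frames:
                snap.positions = pos
                write_xyz(fh, snap, comment=f"step={step}")
        self.metrics.to_csv(out / "metrics.csv", index=False)
        with open(out / "outcome.json", "w") as fh:
            json.dump(self.outcome, fh, indent=2, default=str)
        with open(out / "run.log", "w") as fh:
            fh.write(f"experiment={self.config.experiment} seed={self.config.seed}\n")
            fh.write(f"n_beads_per_ring={self.config.n_beads_per_ring} "
                     f"n_rings={self.config.n_rings} knot={self.config.knot_spec}\n")
            for step, _pos in self.frames:
                fh.write(f"frame at step {step}\n")
            for key, val in self.outcome.items():
                fh.write(f"{key}={val}\n")


def _ring_curve(positions, system, ring):
    from .topology import ClosedCurve

    return ClosedCurve(positions[system.ring_beads(ring)])


def _relax(system, ff, ip, capped=2000, free=3000):
    soft = IntegratorParams(
        dt=ip.dt, gamma=ip.gamma, temperature=ip.temperature,
        seed=ip.seed, force_cap=50.0, skin=ip.skin,
    )
    step_langevin(system, ff, soft, capped)
    step_langevin(system, ff, ip, free)


def _handcuff_run(system, cfg, ff, ip, hcs, ring, sequential=False):
    """Alternate MD and walking until all handcuffs stop (or budget runs out)."""
    rows = []
    frames = []
    step = 0
    active = 0  # sequential mode: index of the currently walking handcuff
    knot = identify_knot(system.curve(ring), seed=cfg.seed).name
    while step < cfg.md_budget:
        step_langevin(system, ff, ip, cfg.advance_every)
        step += cfg.advance_every
        for k, hc in enumerate(hcs):
            if sequential and k != active:
                continue
            advance_walk(system, hc)
        if sequential and hcs[active].complete and active < len(hcs) - 1:
            active += 1
        if step % cfg.sample_every < cfg.advance_every:
            knot = identify_knot(system.curve(ring), seed=cfg.seed).name
            frames.append((step, system.positions.copy()))
            for k, hc in enumerate(hcs):
                rows.append(
                    dict(
                        frame=len(frames) - 1, step=step, ring_id=ring, extruder=k,
                        anchor_left=hc.anchor_a, anchor_right=hc.anchor_b,
                        progress=extrusion_progress(system, hc),
                        stopped_left=hc.halted_a, stopped_right=hc.halted_b,
                        knot=knot,
                    )
                )
            if all(hc.complete for hc in hcs) and knot == "0_1":
                break
    frames.append((step, system.positions.copy()))
    return frames, rows, step


def run_single_tad(cfg: ExperimentConfig, ff=None, ip=None, out_dir=None) -> RunRecord:
    ff = ff or ForceField()
    ip = ip or IntegratorParams(seed=cfg.seed)
    system = single_tad_ring(cfg)
    ring = system.chromatin_rings()[0]
    initial = identify_knot(system.curve(ring), seed=cfg.seed).name
    _relax(system, ff, ip)
    hc = load_handcuff(system, system.meta["extruder_sites"][ring], ring=ring, ff=ff, ip=ip)
    frames, rows, steps = _handcuff_run(system, cfg, ff, ip, [hc], ring)
    final = identify_knot(_ring_curve(frames[-1][1], system, ring), seed=cfg.seed)
    rec = RunRecord(
        config=cfg,
        frames=frames,
        metrics=pd.DataFrame(rows),
        outcome=dict(
            complete=hc.complete,
            status="complete" if hc.complete else "incomplete",
            initial_knot=initial,
            final_knot=final.name,
            steps=steps,
        ),
        system=system,
    )
    if out_dir:
        rec.save(out_dir)
    return rec


def run_three_tad(cfg: ExperimentConfig, ff=None, ip=None, out_dir=None) -> RunRecord:
    ff = ff or ForceField()
    ip = ip or IntegratorParams(seed=cfg.seed)
    system = three_tad_circle(cfg)
    ring = system.chromatin_rings()[0]
    initial = identify_knot(system.curve(ring), seed=cfg.seed).name
    _relax(system, ff, ip)
    hcs = [
        load_handcuff(system, site, ring=ring, ff=ff, ip=ip)
        for site in system.meta["extruder_sites"][ring]
    ]
    frames, rows, steps = _handcuff_run(
        system, cfg, ff, ip, hcs, ring, sequential=cfg.sequential
    )
    final = identify_knot(_ring_curve(frames[-1][1], system, ring), seed=cfg.seed)
    rec = RunRecord(
        config=cfg,
        frames=frames,
        metrics=pd.DataFrame(rows),
        outcome=dict(
            complete=all(hc.complete for hc in hcs),
            status="complete" if all(hc.complete for hc in hcs) else "incomplete",
            initial_knot=initial,
            final_knot=final.name,
            steps=steps,
        ),
        system=system,
    )
    if out_dir:
        rec.save(out_dir)
    return rec


def run_melt_demix(
    cfg: ExperimentConfig, ff=None, ip=None, out_dir=None, post_steps: int = 20_000
) -> RunRecord:
    ff = ff or ForceField()
    ip = ip or IntegratorParams(seed=cfg.seed)
    system, initial_report = equilibrated_melt(cfg, ff=ff, ip=ip)
    rids = system.chromatin_rings()
    r_use = system.sphere_radius + WALL_PAD
    extruders = [
        load_simple_extruder(system, rid, system.meta["extruder_sites"][rid])
        for rid in rids
    ]

    rows = []
    frames = []
    step = 0

    def sample():
        frames.append((step, system.positions.copy()))
        m = interchain_area(tessellate(system.positions, system.ring_index, r_use))
        row = dict(
            frame=len(frames) - 1,
            step=step,
            total_interchain_area=m.total_interchain_area,
        )
        for rid in rids:
            row[f"envelope_{rid}"] = m.per_chain_envelope_area[rid]
        for e in extruders:
            rid = e.ring_id
            row[f"progress_{rid}"] = extrusion_progress(system, e)
            row[f"anchor_left_{rid}"] = e.left_anchor
            row[f"anchor_right_{rid}"] = e.right_anchor
            row[f"stopped_left_{rid}"] = e.left_stopped
            row[f"stopped_right_{rid}"] = e.right_stopped
        rows.append(row)
        return m

    sample()
    migrate_every = 25
    while step < cfg.md_budget:
        step_langevin(system, ff, ip, migrate_every)
        step += migrate_every
        for e in extruders:
            step_simple_extrusion(system, e)
        if step % cfg.sample_every < migrate_every:
            sample()
        if all(e.complete for e in extruders):
            break
    step_langevin(system, ff, ip, post_steps)
    step += post_steps
    sample()
    final_report = melt_topology_report(system, seed=cfg.seed)
    metrics = pd.DataFrame(rows)
    rec = RunRecord(
        config=cfg,
        frames=frames,
        metrics=metrics,
        outcome=dict(
            complete=all(e.complete for e in extruders),
            status="complete" if all(e.complete for e in extruders) else "incomplete",
            steps=step,
            initial_knots=initial_report["knots"],
            final_knots=final_report["knots"],
            initial_linked_pairs=initial_report["linked_pairs"],
            final_linked_pairs=final_report["linked_pairs"],
            initial_interchain_area=float(metrics["total_interchain_area"].iloc[0]),
            final_interchain_area=float(metrics["total_interchain_area"].iloc[-1]),
        ),
        system=system,
    )
    if out_dir:
        rec.save(out_dir)
    return rec


def run_experiment(cfg: ExperimentConfig, **kwargs) -> RunRecord:
    """Dispatch on ``cfg.experiment``."""
    fn = {
        "single_tad": run_single_tad,
        "three_tad": run_three_tad,
        "melt_demix": run_melt_demix,
    }[cfg.experiment]
    return fn(cfg, **kwargs)
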