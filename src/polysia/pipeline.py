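"""End-to-end workflows: LEUS conformational analysis, restrained
torsional sampling, and the restraint free-energy cycle, at toy scale.

Every run is fully determined by its :class:`RunConfig` (explicit seeds,
no global state, no timestamps in outputs) and writes a provenance
record with the config hash, so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fragments import FRAGMENT_SIZES, build_fragment, linkage_torsions
from .free_energy import LambdaSchedule, LambdaSystem1D, cycle_check, osp_run, ti_run
from .hbonds import HBondCriterion, hbond_occurrence
from .karplus import COUPLING_TORSION, ensemble_J
from .leus import (LEBiasPotential, LEGridSpec, free_energy_map, le_build,
                   reweight_weights, us_sample)
from .potentials import PRESETS, build_model_potential
from .restraints import (DihedralRestraint, DistanceRestraint,
                         read_restraint_file, total_restraint_energy)
from .structure import cluster_daura, pucker_series
from .trajectory import TorsionTrajectory
from .units import kt

logger = logging.getLogger("polysia")


@dataclass
class RunConfig:
    """Declarative configuration shared by the pipelines.

    Defaults carry the canonical constants of the protocol: Ng = 36 bins,
    c = 0.005 kJ/mol deposition, clustering cutoffs 0.15/0.25 nm, NOE /
    H-bond / dihedral force constants 500 / 2500 / 100, soft-bond
    kB = 5e4 kJ mol^-1 nm^-2, r0 = 0.25 nm, alpha = 250 (see the
    restraints module), and the two study temperatures 263 K and 300 K.
    """

    preset: str = "dimer1_like"
    temperature: float = 300.0
    seed: int = 0
    le_steps: int = 200_000
    us_steps: int = 400_000
    save_stride: int = 10
    step_size: float = 30.0
    ng: int = 36
    c: float = 0.005
    output_dir: str = "polysia_out"
    experimental_j_csv: str | None = None
    # restrained pipeline
    fragment: str = "tetramer"
    restraint_file: str | None = None
    restrained_steps: int = 4000
    restrained_save_stride: int = 10
    cluster_cutoff: float = 0.15
    # free-energy pipeline
    ti_lambda_points: tuple = (0.0, 0.025, 0.05, 0.1, 0.2, 0.35, 0.5, 0.65,
                               0.8, 0.9, 0.95, 1.0)
    ti_n_equil: int = 5_000
    ti_n_prod: int = 40_000
    restraint_k_dihedral: float = 0.0008  # kJ mol^-1 degree^-2, toy cycle
    restraint_target: float = 60.0

    def validate(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.fragment not in FRAGMENT_SIZES:
            raise ValueError(f"unknown fragment kind {self.fragment!r}")
        for name in ("experimental_j_csv", "restraint_file"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(
                    f"config field {name}: file {p!r} does not exist"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.ti_lambda_points, list):
            cfg.ti_lambda_points = tuple(cfg.ti_lambda_points)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_canonical_dict()))

    def as_canonical_dict(self) -> dict:
        d = asdict(self)
        d["ti_lambda_points"] = list(self.ti_lambda_points)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.as_canonical_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_provenance(cfg: RunConfig, outdir: Path, stage: str,
                      extra: dict | None = None) -> None:
    record = {"stage": stage, "config": cfg.as_canonical_dict(),
              "config_hash": cfg.content_hash(),
              "polysia_version": __version__,
              "numpy_version": np.__version__}
    record.update(extra or {})
    (outdir / f"provenance_{stage}.json").write_text(
        json.dumps(record, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# LEUS pipeline
# ---------------------------------------------------------------------------

def run_leus_pipeline(config: RunConfig) -> dict:
    """Full LEUS workflow: bias build-up on the glycosidic grids, frozen
    umbrella sampling, reweighted free-energy maps, J-coupling table and
    hydrogen-bond report.

    Returns a dict of in-memory results; files (map CSV/PNG, tables,
    provenance) go to ``config.output_dir``.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    pot = build_model_potential(config.preset, temperature=config.temperature)
    logger.info("LEUS pipeline: preset=%s T=%.0fK", config.preset,
                config.temperature)

    if pot.n_torsions >= 4:
        grid_specs = [LEGridSpec(("phi", "psi"), config.ng, c=config.c),
                      LEGridSpec(("omega8", "omega7"), config.ng, c=config.c)]
    elif pot.n_torsions == 2:
        grid_specs = [LEGridSpec(pot.torsion_names, config.ng, c=config.c)]
    else:
        grid_specs = [LEGridSpec(pot.torsion_names, config.ng, c=config.c)]

    biases = []
    for i, spec in enumerate(grid_specs):
        bias = le_build(pot, spec, config.le_steps, seed=config.seed + i,
                        step_size=config.step_size)
        bias.freeze()
        bias.to_json(outdir / f"bias_{'_'.join(spec.torsion_names)}.json")
        biases.append(bias)
    logger.info("LE phase done: %d bias grid(s)", len(biases))

    traj = us_sample(pot, biases, config.us_steps,
                     save_stride=config.save_stride,
                     seed=config.seed + 1000, step_size=config.step_size)
    traj.to_csv(outdir / "us_trajectory.csv")
    weights = reweight_weights(traj, config.temperature)

    maps = {}
    for spec in grid_specs:
        fmap = free_energy_map(traj, spec, config.temperature)
        tag = "_".join(spec.torsion_names)
        fmap.to_csv(outdir / f"gmap_{tag}.csv")
        fmap.plot(outdir / f"gmap_{tag}.png")
        maps[tag] = fmap

    # J couplings available from the sampled torsions
    rows = []
    for coupling, torsion in COUPLING_TORSION.items():
        if torsion not in traj.torsion_names:
            continue
        mean, err = ensemble_J(traj, coupling, weights=weights)
        rows.append({"coupling": coupling, "J_calc": mean, "J_err": err})
    jtable = pd.DataFrame(rows)
    if config.experimental_j_csv:
        exp = pd.read_csv(config.experimental_j_csv)
        jtable = jtable.merge(exp, on="coupling", how="left")
        if "value" in jtable.columns:
            jtable["deviation"] = jtable["J_calc"] - jtable["value"]
    jtable.to_csv(outdir / "jcouplings.csv", index=False,
                  float_format="%.6g")
    _write_markdown_table(jtable, outdir / "jcouplings.md")

    hbonds = None
    if pot.n_torsions >= 4:
        ens, sub_w = _rebuild_dimer_frames(traj, weights, n_max=300)
        hbonds = hbond_occurrence(ens, HBondCriterion(), weights=sub_w)
        hbonds.to_csv(outdir / "hbonds.csv", index=False,
                      float_format="%.4g")

    _write_provenance(config, outdir, "leus",
                      {"n_frames": traj.n_frames,
                       "seeds": [config.seed + i for i in range(len(biases))]
                       + [config.seed + 1000]})
    return {"trajectory": traj, "weights": weights, "maps": maps,
            "jcouplings": jtable, "hbonds": hbonds, "biases": biases}


def _rebuild_dimer_frames(traj: TorsionTrajectory, weights: np.ndarray,
                          n_max: int = 300):
    """Rebuild 3D dimer frames from sampled linkage torsions (evenly
    sub-sampled) for hydrogen-bond analysis."""
    stride = max(1, traj.n_frames // n_max)
    idx = np.arange(0, traj.n_frames, stride)
    coords = []
    ens0 = None
    for i in idx:
        phi, psi = traj.angles("phi")[i], traj.angles("psi")[i]
        w7, w8 = traj.angles("omega7")[i], traj.angles("omega8")[i]
        ens = build_fragment(
            "dimer", [(phi, psi)],
            side_torsions=[{"omega7": w7, "omega8": w8}, {}])
        coords.append(ens.coords[0])
        ens0 = ens
    from .ensemble import ConformerEnsemble

    return (ConformerEnsemble(ens0.atoms, np.asarray(coords), ens0.bonds),
            weights[idx])


def _write_markdown_table(df: pd.DataFrame, path: Path) -> None:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in df.iterrows():
        cells = [f"{v:.3g}" if isinstance(v, float) else str(v)
                 for v in row.values]
        lines.append("| " + " | ".join(cells) + " |")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Restrained pipeline
# ---------------------------------------------------------------------------

def _default_tetramer_restraints() -> list:
    """Built-in restraint set standing in for a restraint file: three
    H-bond distance restraints (HN5 of residues b-d to O8 of the
    preceding residue) and two H7-C7-C6-H6 dihedral restraints at 90
    degrees on residues b and c."""
    from .restraints import (DIHEDRAL_FORCE_CONSTANT, HBOND_FORCE_CONSTANT)

    rs = []
    for i in (1, 2, 3):
        rs.append(DistanceRestraint((i + 1, "HN5"), (i, "O8"), 0.25,
                                    HBOND_FORCE_CONSTANT, style="full"))
    for i in (2, 3):
        rs.append(DihedralRestraint(((i, "H7"), (i, "C7"), (i, "C6"),
                                     (i, "H6")), 90.0,
                                    DIHEDRAL_FORCE_CONSTANT))
    return rs


class _TorsionalOligomerSampler:
    """Metropolis sampling of an oligomer's linkage and side torsions
    with the energy evaluated on the rebuilt Cartesian frame.

    Energy = per-linkage (phi, psi) and per-residue (omega7, omega8)
    terms of the chosen model surface + total restraint energy.
    """

    def __init__(self, kind: str, preset: str, temperature: float,
                 restraints, anomer: str = "alpha") -> None:
        self.kind = kind
        self.n_res = FRAGMENT_SIZES[kind]
        self.n_link = self.n_res - 1
        self.pot = build_model_potential(preset, temperature=temperature)
        self.temperature = temperature
        self.restraints = restraints
        self.anomer = anomer
        # DOF vector: [phi_i, psi_i] per linkage + [omega7_r, omega8_r] per residue
        self.n_dof = 2 * self.n_link + 2 * self.n_res

    def unpack(self, x):
        links = [(x[2 * i], x[2 * i + 1]) for i in range(self.n_link)]
        base = 2 * self.n_link
        side = [{"omega7": x[base + 2 * r], "omega8": x[base + 2 * r + 1]}
                for r in range(self.n_res)]
        return links, side

    def build(self, x):
        links, side = self.unpack(x)
        return build_fragment(self.kind, links, side_torsions=side,
                              anomer=self.anomer)

    def energy(self, x) -> tuple[float, float]:
        """(torsional model energy, restraint energy) of DOF vector x."""
        links, side = self.unpack(x)
        e_t = 0.0
        for i, (phi, psi) in enumerate(links):
            w = side[i]  # the reducing-side residue of linkage i
            e_t += float(self.pot.energy({"phi": phi, "psi": psi,
                                          "omega7": w["omega7"],
                                          "omega8": w["omega8"]}))
        if self.n_link == 0:
            w = side[0]
            e_t += float(self.pot.energy({"phi": 0.0, "psi": 0.0,
                                          "omega7": w["omega7"],
                                          "omega8": w["omega8"]}))
        ens = self.build(x)
        e_r, _ = total_restraint_energy(ens, 0, self.restraints)
        return e_t, e_r

    def run(self, n_steps: int, seed: int, step_size: float = 20.0,
            save_stride: int = 10, x0=None):
        rng = np.random.default_rng(seed)
        x = np.array(x0 if x0 is not None
                     else [60.0, 120.0] * self.n_link
                     + [60.0, 60.0] * self.n_res)
        kbt = kt(self.temperature)
        e_t, e_r = self.energy(x)
        frames, energies = [], []
        for step in range(n_steps):
            j = step % self.n_dof
            xn = x.copy()
            xn[j] = ((xn[j] + rng.uniform(-step_size, step_size) + 180.0)
                     % 360.0 - 180.0)
            et_n, er_n = self.energy(xn)
            de = (et_n + er_n) - (e_t + e_r)
            if de <= 0 or rng.random() < np.exp(-de / kbt):
                x, e_t, e_r = xn, et_n, er_n
            if (step + 1) % save_stride == 0:
                frames.append(x.copy())
                energies.append((e_t, e_r))
        return np.asarray(frames), np.asarray(energies)


def run_restrained_pipeline(config: RunConfig) -> dict:
    """Restrained torsional sampling of an oligomer with violation,
    cluster and puckering reports."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.restraint_file:
        restraints = read_restraint_file(config.restraint_file)
    else:
        restraints = _default_tetramer_restraints()
        if config.fragment != "tetramer":
            restraints = []
    preset = ("dimer2_like" if config.fragment in ("tetramer",)
              else config.preset if config.preset in ("dimer1_like",
                                                      "dimer2_like")
              else "dimer1_like")
    sampler = _TorsionalOligomerSampler(
        config.fragment, preset, config.temperature, restraints,
        anomer="beta" if config.fragment == "tetramer" else "alpha")
    frames, energies = sampler.run(config.restrained_steps, config.seed,
                                   save_stride=config.restrained_save_stride)
    logger.info("restrained sampling: %d saved frames", len(frames))

    # rebuild saved frames into one ensemble
    coords = []
    ens0 = None
    for x in frames:
        ens0 = sampler.build(x)
        coords.append(ens0.coords[0])
    from .ensemble import ConformerEnsemble

    ens = ConformerEnsemble(ens0.atoms, np.asarray(coords), ens0.bonds)
    ens.to_pdb(outdir / "restrained_ensemble.pdb")

    # violation report: one row per restraint, per-frame mean and max
    rows = []
    for k, r in enumerate(restraints):
        per_frame = np.array([
            _restraint_violation(ens, f, r) for f in range(ens.n_frames)])
        rows.append({"restraint": k, "type": type(r).__name__,
                     "mean_violation": float(per_frame.mean()),
                     "max_violation": float(per_frame.max())})
    violations = pd.DataFrame(rows)
    violations.to_csv(outdir / "violations.csv", index=False,
                      float_format="%.6g")

    clusters = cluster_daura(ens, config.cluster_cutoff)
    clusters.to_frame().to_csv(outdir / "clusters.csv", index=False)
    puckers = pd.concat([pucker_series(ens, r).assign(residue=r)
                         for r in range(1, sampler.n_res + 1)])
    puckers.to_csv(outdir / "puckering.csv", index=False,
                   float_format="%.5g")
    audit_total, audit_breakdown = (
        total_restraint_energy(ens, ens.n_frames - 1, restraints)
        if restraints else (0.0, []))
    _write_provenance(config, outdir, "restrained",
                      {"n_frames": int(ens.n_frames),
                       "final_restraint_energy": audit_total})
    return {"ensemble": ens, "violations": violations, "clusters": clusters,
            "puckering": puckers, "restraints": restraints,
            "final_restraint_energy": audit_total,
            "final_breakdown": audit_breakdown}


def _restraint_violation(ens, frame, r) -> float:
    from .geometry import measure_torsion
    from .units import wrap_angle_scalar

    if isinstance(r, DistanceRestraint):
        d = float(np.linalg.norm(ens.position(frame, *r.atom1)
                                 - ens.position(frame, *r.atom2)))
        dev = d - r.r0
        return max(dev, 0.0) if r.style == "half" else abs(dev)
    if isinstance(r, DihedralRestraint):
        chi = measure_torsion(*(ens.position(frame, *a) for a in r.atoms))
        return abs(wrap_angle_scalar(chi - r.target))
    d = float(np.linalg.norm(ens.position(frame, *r.atom1)
                             - ens.position(frame, *r.atom2)))
    return abs(d - r.r0_b)


# ---------------------------------------------------------------------------
# Free-energy pipeline
# ---------------------------------------------------------------------------

def run_freeenergy_pipeline(config: RunConfig) -> dict:
    """Restraint free-energy cycle on the double-well torsion toy.

    State A: unrestrained double well.  State B: A plus a lambda-coupled
    harmonic dihedral restraint (TI along the schedule).  State C: the
    restraint removed again by one-step perturbation.  The direct
    A->B reference from 1-degree quadrature closes the cycle.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    barrier, delta, m1 = 8.0, 2.0, 60.0
    k_r = config.restraint_k_dihedral
    target = config.restraint_target
    system = LambdaSystem1D.restrained_double_well(barrier, delta, m1, k_r,
                                                   target)
    schedule = LambdaSchedule(tuple(config.ti_lambda_points),
                              config.ti_n_equil, config.ti_n_prod,
                              seed=config.seed)
    ti = ti_run(system, schedule, config.temperature)

    # restrained (state B) ensemble for the OSP release
    xs, _ = system.sample(1.0, config.ti_n_prod * 4, system.x0,
                          (config.seed * 2617 + 11) % (2 ** 31))
    u_res = 0.5 * k_r * ((np.asarray(xs) - target + 180.0) % 360.0 - 180.0) ** 2
    osp = osp_run(u_res, config.temperature)

    # state C equals state A (restraint removed), so the direct A->C
    # reference is zero; the quadrature dG(A->B) checks the TI leg alone
    quad_ab = _quadrature_delta_g(system, config.temperature)
    report = cycle_check(ti, osp, direct_delta_g=0.0)
    payload = {"ti": ti.to_dict(), "osp": osp.to_dict(),
               "ti_quadrature_reference": quad_ab,
               "cycle": report.to_dict()}
    (outdir / "free_energy.json").write_text(json.dumps(payload, indent=1))
    _write_provenance(config, outdir, "free_energy")
    return {"ti": ti, "osp": osp, "cycle": report, "direct": quad_ab}


def _quadrature_delta_g(system: LambdaSystem1D, temperature: float) -> float:
    """Exact dG(A->B) of switching the system's restraint on, from
    1-degree grid quadrature of the two partition functions."""
    x = np.arange(-180.0, 180.0, 1.0)
    kbt = kt(temperature)
    e0 = system.energy(x, 0.0)
    e1 = system.energy(x, 1.0)
    z0 = np.exp(-(e0 - e0.min()) / kbt).sum()
    z1 = np.exp(-(e1 - e0.min()) / kbt).sum()
    return float(-kbt * np.log(z1 / z0))
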