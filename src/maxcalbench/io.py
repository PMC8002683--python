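"""Trajectory and manifest readers/writers, fixture generators and
report rendering.

Trajectories are plain tab-separated files (one row per frame, columns
``time_s``, ``A`` and optionally ``B``), one file per trajectory, with a
JSON manifest per ensemble recording the circuit, rate constants, frame
interval, seeds and the file list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .ssa import FrameSeries, SimulationConfig

SCHEMA_VERSION = 1


class InputError(ValueError):
    """Malformed trajectory or manifest input."""


@dataclass
class Manifest:
    circuit: str
    delta_t: float
    rates: dict
    seeds: dict
    files: list[str]          # relative paths, grouped per replicate
    replicates: list[list[str]]
    schema_version: int = SCHEMA_VERSION
    software_version: str = __version__
    extra: dict = field(default_factory=dict)


def write_frame_series(path: Path, series: FrameSeries) -> None:
    header = "time_s\t" + "\t".join(series.species_labels)
    lines = [header]
    for k in range(series.n_frames):
        row = [f"{k * series.delta_t:.6g}"]
        row += [str(int(v)) for v in series.counts[k]]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_frame_series(path: Path, delta_t: float | None = None) -> FrameSeries:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise InputError(f"{path}: empty trajectory file")
    header = lines[0].split("\t")
    if header[0] != "time_s" or len(header) < 2:
        raise InputError(f"{path}: expected header 'time_s<TAB>A[<TAB>B]'")
    labels = header[1:]
    times, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise InputError(f"{path}:{lineno}: ragged row "
                             f"({len(cells)} cells, expected {len(header)})")
        times.append(float(cells[0]))
        vals = []
        for c in cells[1:]:
            try:
                v = int(c)
            except ValueError as exc:
                raise InputError(
                    f"{path}:{lineno}: non-integer count {c!r}") from exc
            if v < 0:
                raise InputError(f"{path}:{lineno}: negative count {v}")
            vals.append(v)
        rows.append(vals)
    times = np.asarray(times)
    if len(times) >= 2:
        steps = np.diff(times)
        dt = float(steps[0])
        if not np.allclose(steps, dt, rtol=1e-6):
            raise InputError(f"{path}: non-uniform frame times")
    elif delta_t is not None:
        dt = float(delta_t)
    else:
        raise InputError(f"{path}: single frame and no --delta-t given")
    if delta_t is not None and not np.isclose(dt, delta_t, rtol=1e-6):
        raise InputError(
            f"{path}: frame interval {dt} differs from expected {delta_t}")
    return FrameSeries(dt, np.asarray(rows, dtype=np.int64), labels)


def write_ensemble(
    out_dir,
    circuit: str,
    config: SimulationConfig,
    replicates: list[list[FrameSeries]],
    params: dict | None = None,
) -> Manifest:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rep_files: list[list[str]] = []
    for r, trajs in enumerate(replicates):
        names = []
        for i, series in enumerate(trajs):
            name = f"rep{r:02d}_traj{i:03d}.tsv"
            write_frame_series(out_dir / name, series)
            names.append(name)
        rep_files.append(names)
    manifest = Manifest(
        circuit=circuit,
        delta_t=config.delta_t,
        rates=dict(params or {}),
        seeds={"rng_seed": config.rng_seed},
        files=[f for grp in rep_files for f in grp],
        replicates=rep_files,
        extra={
            "t_end": config.t_end, "burn_in": config.burn_in,
            "n_trajectories": config.n_trajectories,
            "n_replicates": config.n_replicates,
        },
    )
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest.__dict__, indent=2, sort_keys=True) + "\n")
    return manifest


def read_trajectories(
    path,
    delta_t: float | None = None,
) -> tuple[list[list[FrameSeries]], Manifest]:
    """Read an ensemble directory: either manifest-described replicates
    or a bare directory of TSV files (one replicate; requires
    ``delta_t`` if files hold a single frame)."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if manifest_path.exists():
        raw = json.loads(manifest_path.read_text())
        manifest = Manifest(**{k: raw[k] for k in (
            "circuit", "delta_t", "rates", "seeds", "files", "replicates",
            "schema_version", "software_version", "extra")})
        replicates = []
        for grp in manifest.replicates:
            trajs = []
            for name in grp:
                fp = path / name
                if not fp.exists():
                    raise InputError(f"manifest lists missing file {name}")
                trajs.append(read_frame_series(fp, manifest.delta_t))
            replicates.append(trajs)
        return replicates, manifest
    files = sorted(path.glob("*.tsv"))
    if not files:
        raise InputError(f"{path}: no manifest.json and no *.tsv files")
    trajs = [read_frame_series(f, delta_t) for f in files]
    dts = {t.delta_t for t in trajs}
    if len(dts) != 1:
        raise InputError(f"{path}: trajectories mix frame intervals {sorted(dts)}")
    manifest = Manifest(
        circuit="unknown", delta_t=trajs[0].delta_t, rates={}, seeds={},
        files=[f.name for f in files], replicates=[[f.name for f in files]],
    )
    return [trajs], manifest


# ---------------------------------------------------------------------------
# deterministic fixtures for tests and examples

def make_fixture(kind: str, seed: int = 1) -> list[FrameSeries]:
    """Small, deterministic trajectory sets used across the test suite.

    * ``birth_death``: a linear birth-death chain sampled every 300 s.
    * ``square_wave``: a noiseless two-level wave with 50-frame dwells.
    * ``tiny_sgaa``: a short two-state switch with both occupancy
      clusters visited repeatedly (synthetic stand-in for circuit data).
    * ``tiny_ts``: an anticorrelated two-species toggle sketch.
    """
    rng = np.random.default_rng(seed)
    dt = 300.0
    if kind == "birth_death":
        lam, mu, n_frames = 0.05, 0.002, 500
        from .cgm import CGMParamsSGAA, sgaa_cgm_network
        from .ssa import SimulationConfig, simulate_ssa
        net = sgaa_cgm_network(CGMParamsSGAA(lam, 0.0, 1.0, mu))
        cfg = SimulationConfig(t_end=(n_frames - 1) * dt + dt, delta_t=dt,
                               burn_in=0.0, rng_seed=seed)
        out = simulate_ssa(net, cfg)
        return [FrameSeries(dt, t.counts[:n_frames], ["A"]) for t in out]
    if kind == "square_wave":
        low, high, dwell, n_frames = 3, 40, 50, 1000
        counts = np.array([(low if (k // dwell) % 2 == 0 else high)
                           for k in range(n_frames)])
        return [FrameSeries(dt, counts, ["A"])]
    if kind == "tiny_sgaa":
        # alternating low/high dwell states with Poisson occupation noise
        n_frames, dwell = 480, 40
        level = np.array([(5 if (k // dwell) % 2 == 0 else 45)
                          for k in range(n_frames)])
        counts = rng.poisson(level)
        return [FrameSeries(dt, counts, ["A"])]
    if kind == "tiny_ts":
        n_frames, dwell = 480, 60
        hi = np.array([(k // dwell) % 2 == 0 for k in range(n_frames)])
        A = rng.poisson(np.where(hi, 40, 2))
        B = rng.poisson(np.where(hi, 2, 40))
        return [FrameSeries(dt, np.stack([A, B], axis=1), ["A", "B"])]
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# report rendering

def _fmt_rate(stats: dict | None) -> str:
    if not stats:
        return "-"
    mean = stats["mean"]
    if stats.get("sd") is None:
        return f"{mean * 1e3:.2g}e-3"
    return f"({mean * 1e3:.2g} +/- {stats['sd'] * 1e3:.2g})e-3"


def render_report(report) -> str:
    """Aligned text table: the True row first, then one row per model
    with mean +/- sd of each effective rate (all s^-1, displayed in
    units of 1e-3 s^-1 as is conventional for these circuits)."""
    rows = [("Method", "peff (s-1)", "peff* (s-1)", "reff (s-1)")]
    t = report.true_rates
    rows.append(("True", f"{t['peff'] * 1e3:.2g}e-3",
                 f"{t['peff_star'] * 1e3:.2g}e-3", f"{t['reff'] * 1e3:.2g}e-3"))
    order = {"dm": "DM", "cgm": "CGM", "maxcal": "MaxCal"}
    for key, label in order.items():
        if key not in report.summary:
            continue
        s = report.summary[key]
        rows.append((label, _fmt_rate(s.get("peff")),
                     _fmt_rate(s.get("peff_star")), _fmt_rate(s.get("reff"))))
    widths = [max(len(r[c]) for r in rows) for c in range(4)]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
             for row in rows]
    return "\n".join(lines)


def report_to_json(report) -> dict:
    """JSON twin of the benchmark report."""
    return {
        "schema_version": SCHEMA_VERSION,
        "circuit": report.circuit,
        "true_rates": report.true_rates,
        "summary": report.summary,
        "m": report.m,
        "nmax": report.nmax,
        "failures": report.failures,
        "per_replicate": {
            model: [
                {
                    "params": r.params,
                    "log_likelihood": r.log_likelihood,
                    "effective_rates": r.effective_rates,
                    "converged": r.converged,
                    "m": r.m, "nmax": r.nmax,
                    "unit_op_seconds": r.unit_op_seconds,
                    "total_seconds": r.total_seconds,
                    "replicate": r.replicate,
                    "diagnostics": r.diagnostics,
                }
                for r in results
            ]
            for model, results in report.per_replicate.items()
        },
    }
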