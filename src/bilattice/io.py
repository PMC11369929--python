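"""Text-first artifact I/O: trajectories, snapshots, scan tables, manifests.

All quantitative outputs are delimited text with named columns; snapshots
are plain character maps.  Readers enforce the type invariants and refuse
malformed files rather than repairing them.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .engine import BilayerState
from .errors import InvalidParameterError, ParseError
from .observables import ObservableSummary, Trajectory

__all__ = [
    "RunManifest",
    "write_trajectory",
    "read_trajectory",
    "snapshot_text",
    "pair_text",
    "write_snapshot",
    "read_snapshot",
    "write_summaries",
    "read_summaries",
    "write_manifest",
    "read_manifest",
]

_TRAJ_COLUMNS = ("t", "rho_plus", "rho_minus", "f_CC", "f_CD", "f_DC", "f_DD")

#: pair-coded snapshot characters (CC, DD, CD, DC)
PAIR_CHARS = {"CC": "B", "DD": "R", "CD": "G", "DC": "K"}


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------- trajectory

def write_trajectory(trajectory: Trajectory, path) -> None:
    """Write a trajectory as tab-delimited text; round-trips bit-exactly."""
    lines = ["# bilattice trajectory v1"]
    lines.append(f"# N={trajectory.N}")
    lines.append(f"# absorbed={trajectory.absorbed if trajectory.absorbed else '-'}")
    lines.append(f"# absorbed_at={trajectory.absorbed_at if trajectory.absorbed_at is not None else '-'}")
    lines.append("\t".join(_TRAJ_COLUMNS))
    for k in range(len(trajectory)):
        row = [str(int(trajectory.times[k])), _fmt(trajectory.rho_plus[k]), _fmt(trajectory.rho_minus[k])]
        row += [_fmt(v) for v in trajectory.pair_freqs[k]]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path) -> Trajectory:
    """Parse a trajectory file, enforcing the pair-frequency invariants."""
    raw = Path(path).read_text().splitlines()
    if not raw:
        raise ParseError("empty trajectory file", line=1)
    meta = {}
    header_idx = None
    for ln, line in enumerate(raw, start=1):
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        if line.split("\t") == list(_TRAJ_COLUMNS):
            header_idx = ln
            break
        raise ParseError(f"expected column header {_TRAJ_COLUMNS}, got {line!r}", line=ln)
    if header_idx is None:
        raise ParseError("no column header found", line=len(raw))
    if "N" not in meta:
        raise ParseError("missing '# N=' header", line=1)
    times, rp, rm, pf = [], [], [], []
    for ln, line in enumerate(raw[header_idx:], start=header_idx + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise ParseError(f"expected 7 columns, got {len(parts)}", line=ln)
        try:
            times.append(int(parts[0]))
            vals = [float(p) for p in parts[1:]]
        except ValueError as exc:
            raise ParseError(str(exc), line=ln) from None
        rp.append(vals[0])
        rm.append(vals[1])
        pf.append(vals[2:])
        if abs(sum(vals[2:]) - 1.0) > 1e-12:
            raise ParseError("pair frequencies do not sum to 1", line=ln)
        if abs(vals[2] + vals[3] - vals[0]) > 1e-12 or abs(vals[2] + vals[4] - vals[1]) > 1e-12:
            raise ParseError("pair frequencies inconsistent with layer frequencies", line=ln)
    if not times:
        raise ParseError("trajectory contains no samples", line=len(raw))
    absorbed = meta.get("absorbed", "-")
    absorbed_at = meta.get("absorbed_at", "-")
    traj = Trajectory(
        times=np.array(times, dtype=np.int64),
        rho_plus=np.array(rp),
        rho_minus=np.array(rm),
        pair_freqs=np.array(pf),
        N=int(meta["N"]),
        absorbed=None if absorbed == "-" else absorbed,
        absorbed_at=None if absorbed_at == "-" else int(absorbed_at),
    )
    traj.validate()
    return traj


# ---------------------------------------------------------------- snapshots

def snapshot_text(state: BilayerState, r=None, K=None, seed=None) -> str:
    """Character-map snapshot: header, layer +1 block, blank line, layer -1
    block; 'C'/'D' per cell."""
    hdr = f"# bilattice snapshot L={state.L} r={r if r is not None else '-'} " \
          f"K={K if K is not None else '-'} t={state.t} seed={seed if seed is not None else '-'}"
    blocks = []
    for slot in (1, 0):  # layer +1 first
        grid = state.strategies[slot]
        blocks.append("\n".join("".join("C" if c else "D" for c in row) for row in grid))
    return hdr + "\n" + blocks[0] + "\n\n" + blocks[1] + "\n"


def pair_text(state: BilayerState) -> str:
    """Pair-coded map with characters B/R/G/K for CC/DD/CD/DC."""
    plus, minus = state.strategies[1], state.strategies[0]
    lookup = {(1, 1): "B", (0, 0): "R", (1, 0): "G", (0, 1): "K"}
    return "\n".join(
        "".join(lookup[(int(plus[i, j]), int(minus[i, j]))] for j in range(state.L))
        for i in range(state.L)
    ) + "\n"


def write_snapshot(state: BilayerState, path, r=None, K=None, seed=None) -> None:
    Path(path).write_text(snapshot_text(state, r=r, K=K, seed=seed))


def read_snapshot(path) -> tuple[BilayerState, dict]:
    """Parse a snapshot file; returns the state and the header metadata."""
    raw = Path(path).read_text().splitlines()
    if not raw or not raw[0].startswith("# bilattice snapshot"):
        raise ParseError("missing snapshot header", line=1)
    meta = {}
    for tok in raw[0].split()[3:]:
        key, _, val = tok.partition("=")
        meta[key] = val
    try:
        L = int(meta["L"])
    except (KeyError, ValueError):
        raise ParseError("snapshot header lacks a valid L", line=1) from None
    body = raw[1:]
    try:
        blank = body.index("")
    except ValueError:
        raise ParseError("snapshot blocks must be separated by a blank line", line=len(raw)) from None
    block_plus, block_minus = body[:blank], [ln for ln in body[blank + 1:] if ln.strip()]
    grids = []
    for offset, block in ((2, block_plus), (blank + 3, block_minus)):
        if len(block) != L:
            raise ParseError(f"expected {L} rows per block, got {len(block)}", line=offset)
        grid = np.zeros((L, L), dtype=np.int8)
        for i, line in enumerate(block):
            if len(line) != L or set(line) - {"C", "D"}:
                raise ParseError(f"invalid snapshot row {line!r}", line=offset + i)
            grid[i] = [1 if ch == "C" else 0 for ch in line]
        grids.append(grid)
    t = int(meta.get("t", 0))
    return BilayerState(np.stack([grids[1], grids[0]]), t=t), meta


# ---------------------------------------------------------------- summaries

_SUMMARY_COLUMNS = (
    "r", "K", "L", "seed", "rho_bar_plus", "rho_bar_minus", "chi_plus", "chi_minus",
    "phi", "chi_phi", "kappa", "f_CC", "f_CD", "f_DC", "f_DD", "n_samples", "absorbed",
)


def write_summaries(summaries: list[ObservableSummary], path) -> None:
    """One tab-delimited row per (r, K, L, seed) point."""
    lines = ["\t".join(_SUMMARY_COLUMNS)]
    for s in summaries:
        row = [
            _fmt(s.r) if s.r is not None else "-",
            _fmt(s.K) if s.K is not None else "-",
            str(s.L) if s.L is not None else "-",
            str(s.seed) if s.seed is not None else "-",
            _fmt(s.rho_bar_plus), _fmt(s.rho_bar_minus),
            _fmt(s.chi_plus), _fmt(s.chi_minus),
            _fmt(s.Phi), _fmt(s.chi_Phi), _fmt(s.kappa),
            *(_fmt(v) for v in s.pair_means),
            str(s.n_samples),
            s.absorbed if s.absorbed else "-",
        ]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_summaries(path) -> list[ObservableSummary]:
    raw = Path(path).read_text().splitlines()
    if not raw or raw[0].split("\t") != list(_SUMMARY_COLUMNS):
        raise ParseError("missing or invalid summary header", line=1)
    out = []
    for ln, line in enumerate(raw[1:], start=2):
        if not line.strip():
            continue
        p = line.split("\t")
        if len(p) != len(_SUMMARY_COLUMNS):
            raise ParseError(f"expected {len(_SUMMARY_COLUMNS)} columns, got {len(p)}", line=ln)
        try:
            out.append(ObservableSummary(
                rho_bar_plus=float(p[4]), rho_bar_minus=float(p[5]),
                chi_plus=float(p[6]), chi_minus=float(p[7]),
                Phi=float(p[8]), chi_Phi=float(p[9]), kappa=float(p[10]),
                pair_means=tuple(float(v) for v in p[11:15]),
                n_samples=int(p[15]),
                r=None if p[0] == "-" else float(p[0]),
                K=None if p[1] == "-" else float(p[1]),
                L=None if p[2] == "-" else int(p[2]),
                seed=None if p[3] == "-" else int(p[3]),
                absorbed=None if p[16] == "-" else p[16],
            ))
        except ValueError as exc:
            raise ParseError(str(exc), line=ln) from None
    return out


# ---------------------------------------------------------------- manifests

@dataclass
class RunManifest:
    """Provenance of one run: everything needed to reproduce its outputs."""

    params: dict
    seed: int
    version: str
    outputs: list[str] = field(default_factory=list)
    started: float = field(default_factory=time.time)
    finished: float | None = None


def write_manifest(manifest: RunManifest, path) -> None:
    """Write-once JSON manifest; refuses to overwrite an existing file."""
    p = Path(path)
    if p.exists():
        raise InvalidParameterError(f"manifest {p} already exists (manifests are write-once)")
    p.write_text(json.dumps(asdict(manifest), indent=2) + "\n")


def read_manifest(path) -> RunManifest:
    data = json.loads(Path(path).read_text())
    return RunManifest(**data)
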