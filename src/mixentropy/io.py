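"""File formats: lattice frame text files, extended-XYZ trajectories,
delimited particle tables, GRO coordinate files (read-only) and TSV result
rows.

Readers validate and reject malformed input rather than coercing it; the
lattice and XYZ writers round-trip bit-exactly with their readers.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .estimate import EntropyEstimate
from .lattice_sim import LatticeEnsemble
from .particles import ParticleSnapshot, Trajectory

__all__ = [
    "write_lattice_frames", "read_lattice_frames",
    "write_xyz", "read_xyz", "read_csv_particles", "read_gro",
    "read_particles", "write_manifest", "result_row", "RESULT_HEADER",
]


# ---------------------------------------------------------------------------
# lattice frame dialect:
#   "# L=<int> alphabet=<csv> frame=<int>" header per frame, L rows of L
#   whitespace-separated integers, frames separated by one blank line.


def write_lattice_frames(ensemble: LatticeEnsemble, path) -> None:
    frames = ensemble.frames
    if frames.ndim != 3:
        raise ValueError("only 2D lattice ensembles are serialised")
    alpha_csv = ",".join(str(a) for a in ensemble.alphabet)
    with open(path, "w") as fh:
        for k, frame in enumerate(frames):
            fh.write(f"# L={frame.shape[0]} alphabet={alpha_csv} frame={k}\n")
            for row in frame:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
            fh.write("\n")


def read_lattice_frames(path) -> LatticeEnsemble:
    frames, alphabet, L = [], None, None
    rows: list[list[int]] = []

    def flush(lineno):
        nonlocal rows
        if not rows:
            return
        if len(rows) != L:
            raise ValueError(f"line {lineno}: frame has {len(rows)} rows, expected {L}")
        frames.append(np.array(rows, dtype=np.int64))
        rows = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                flush(lineno)
                continue
            if line.startswith("#"):
                fields = dict(kv.split("=", 1) for kv in line[1:].split())
                if "L" not in fields or "alphabet" not in fields:
                    raise ValueError(f"line {lineno}: malformed header {line!r}")
                L_here = int(fields["L"])
                alpha_here = tuple(int(a) for a in fields["alphabet"].split(","))
                if L is None:
                    L, alphabet = L_here, alpha_here
                elif (L_here, alpha_here) != (L, alphabet):
                    raise ValueError(f"line {lineno}: inconsistent header")
                continue
            row = [int(v) for v in line.split()]
            if L is None:
                raise ValueError(f"line {lineno}: data before header")
            if len(row) != L:
                raise ValueError(f"line {lineno}: row of length {len(row)}, expected {L}")
            rows.append(row)
        flush("end of file")
    if not frames:
        raise ValueError("no frames found")
    stack = np.stack(frames)
    if not np.isin(stack, np.asarray(alphabet)).all():
        raise ValueError("entries outside the declared alphabet")
    return LatticeEnsemble(frames=stack, alphabet=alphabet)


# ---------------------------------------------------------------------------
# extended XYZ:
#   count line; comment line with box="Lx Ly [Lz]" time=<float> key=value
#   pairs; then "label x y [z]" rows.  Axes without a box length are
#   non-periodic (box then only bounds the data).


def _fmt_float(x: float) -> str:
    return repr(float(x))


def write_xyz(traj, path) -> None:
    snaps = traj.snapshots if isinstance(traj, Trajectory) else [traj]
    with open(path, "w") as fh:
        for snap in snaps:
            fh.write(f"{snap.n}\n")
            box = " ".join(_fmt_float(b) for b in snap.box)
            per = " ".join("T" if p else "F" for p in snap.periodic)
            t = "" if snap.time is None else f' time={_fmt_float(snap.time)}'
            fh.write(f'box="{box}" periodic="{per}"{t}\n')
            for lab, p in zip(snap.labels, snap.positions):
                fh.write(str(lab) + " " + " ".join(_fmt_float(x) for x in p) + "\n")


def _parse_comment(line: str) -> dict:
    out, i = {}, 0
    while i < len(line):
        if line[i].isspace():
            i += 1
            continue
        eq = line.index("=", i)
        key = line[i:eq]
        if eq + 1 < len(line) and line[eq + 1] == '"':
            end = line.index('"', eq + 2)
            out[key] = line[eq + 2:end]
            i = end + 1
        else:
            end = line.find(" ", eq)
            if end == -1:
                end = len(line)
            out[key] = line[eq + 1:end]
            i = end
    return out


def read_xyz(path) -> Trajectory:
    snaps = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, lineno = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"line {i + 1}: expected particle count") from exc
        fields = _parse_comment(lines[i + 1])
        if "box" not in fields:
            raise ValueError(f"line {i + 2}: comment line must carry box=\"...\"")
        box = np.array([float(v) for v in fields["box"].split()])
        periodic = np.array([c == "T" for c in fields.get(
            "periodic", "T " * len(box)).split()])
        time = float(fields["time"]) if "time" in fields else None
        labels, pos = [], []
        for row in lines[i + 2:i + 2 + n]:
            parts = row.split()
            if len(parts) != 1 + len(box):
                raise ValueError(f"malformed particle row {row!r}")
            labels.append(parts[0])
            pos.append([float(v) for v in parts[1:]])
        if len(pos) != n:
            raise ValueError("truncated frame")
        snaps.append(ParticleSnapshot(np.array(pos), np.array(labels), box,
                                      periodic, time))
        i += 2 + n
    if not snaps:
        raise ValueError("no frames found")
    if any(s.time is None for s in snaps):
        snaps = [ParticleSnapshot(s.positions, s.labels, s.box, s.periodic, float(k))
                 for k, s in enumerate(snaps)]
    return Trajectory(snaps)


def read_csv_particles(path, box, periodic=True, delimiter=None) -> Trajectory:
    """Single snapshot from delimited columns: id, label, x, y[, z].

    The box is not stored in the file and must be supplied.
    """
    labels, pos = [], []
    box = np.atleast_1d(np.asarray(box, dtype=float))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split() if delimiter is None \
                else line.split(delimiter)
            if lineno == 1 and not _is_number(parts[-1]):
                continue  # header row
            if len(parts) != 2 + len(box):
                raise ValueError(f"line {lineno}: expected id,label,"
                                 + ",".join("xyz"[:len(box)]))
            labels.append(parts[1])
            pos.append([float(v) for v in parts[2:]])
    if not pos:
        raise ValueError("no particle rows found")
    snap = ParticleSnapshot(np.array(pos), np.array(labels), box, periodic, 0.0)
    return Trajectory([snap])


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_gro(path, bead: str, label_map: dict) -> Trajectory:
    """One reference bead per residue from a GRO coordinate file.

    ``bead`` names the atom selected per residue (e.g. the phosphate bead
    of a coarse-grained lipid); ``label_map`` maps residue names to
    component labels.  Residues not in the map raise.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    sel = u.select_atoms(f"name {bead}")
    if len(sel) == 0:
        raise ValueError(f"no atoms named {bead!r} in {path}")
    resnames = sel.resnames
    unknown = sorted(set(resnames) - set(label_map))
    if unknown:
        raise ValueError(f"unmapped residue names: {unknown}")
    labels = np.array([label_map[r] for r in resnames])
    box = u.dimensions[:3].astype(float) / 10.0  # Angstrom -> nm (GRO units)
    snap = ParticleSnapshot(sel.positions.astype(float) / 10.0, labels, box,
                            periodic=True, time=0.0)
    return Trajectory([snap])


def read_particles(path, format: str = "auto", box=None, bead: str | None = None,
                   label_map: dict | None = None) -> Trajectory:
    """Dispatching reader: extended XYZ, delimited columns, or GRO."""
    path = Path(path)
    if format == "auto":
        format = {".xyz": "xyz", ".gro": "gro", ".csv": "csv",
                  ".tsv": "csv", ".txt": "csv"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format of {path.name}; pass format=")
    if format == "xyz":
        return read_xyz(path)
    if format == "csv":
        if box is None:
            raise ValueError("delimited input needs an explicit box")
        return read_csv_particles(path, box)
    if format == "gro":
        if bead is None or label_map is None:
            raise ValueError("GRO input needs bead= and label_map=")
        return read_gro(path, bead, label_map)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# results and manifests


RESULT_HEADER = "time\testimator\tparams\tvalue_nats\tn_samples\tn_states_observed\tskipped\tundersampled"


def result_row(est: EntropyEstimate, time: float | None = None,
               params: str = "") -> str:
    t = "" if time is None else f"{time:g}"
    return "\t".join([t, est.estimator, params, f"{est.value:.6f}",
                      f"{est.n_samples:g}", str(est.n_states_observed),
                      str(est.n_skipped), str(est.undersampled).lower()])


def write_manifest(path, config: dict) -> None:
    """Echo the fully resolved run configuration next to its outputs."""
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
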