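"""Readers and writers for the standard interchange formats (SIF, MIDAS).

SIF (Cytoscape simple interaction format): one interaction per line,
``source relation target`` separated by whitespace or tabs. Accepted
relations: ``1``/``activates`` (sign +1) and ``-1``/``inhibits`` (sign -1).

MIDAS: a CSV whose header encodes the experimental design via column
prefixes — ``TR:<x>`` a stimulus treatment, ``TR:<x>i`` an inhibitor
(trailing-"i" convention), ``DA:<x>`` the acquisition time of readout x,
``DV:<x>`` its measured value. An optional ``TR:...CellLine`` column is
ignored. Each row is one condition at one acquisition time; values are read
untouched (normalization is a separate, explicit step).
"""

from __future__ import annotations

import csv
import math
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional

import numpy as np

from .types import Condition, Dataset, PKN, Roles

__all__ = [
    "read_sif",
    "write_sif",
    "read_midas",
    "write_midas",
    "select_time",
    "normalize",
    "discretize",
    "discretize_scaled",
]

_RELATION_SIGNS = {"1": 1, "+1": 1, "activates": 1, "-1": -1, "inhibits": -1}


class FormatError(ValueError):
    """Malformed input file."""


def read_sif(path) -> PKN:
    """Parse a SIF file into a PKN with empty roles (roles come from MIDAS/config)."""
    nodes: set = set()
    edges: set = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) == 1:
                nodes.add(fields[0])  # isolated node, no interactions
                continue
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            src, rel, *targets = fields
            if rel not in _RELATION_SIGNS:
                raise FormatError(f"{path}:{lineno}: unknown relation token {rel!r}")
            sign = _RELATION_SIGNS[rel]
            nodes.add(src)
            for tgt in targets:
                nodes.add(tgt)
                edges.add((src, sign, tgt))
    return PKN(frozenset(nodes), frozenset(edges))


def write_sif(pkn: PKN, path) -> None:
    with open(path, "w") as fh:
        for (u, s, v) in pkn.sorted_edges:
            fh.write(f"{u}\t{1 if s > 0 else -1}\t{v}\n")
        # isolated nodes cannot be represented as interactions; SIF drops them
        covered = {u for (u, _, v) in pkn.edges} | {v for (u, _, v) in pkn.edges}
        for n in sorted(pkn.nodes - covered):
            fh.write(f"{n}\n")


def _parse_midas_header(header):
    stimuli, inhibitables, readouts = [], [], []
    colroles = {}  # index -> (kind, name)
    for i, col in enumerate(header):
        col = col.strip()
        if col.startswith("TR:"):
            name = col[3:]
            if name.endswith("CellLine") or name.lower() == "cellline":
                colroles[i] = ("ignore", name)
            elif name.endswith("i") and len(name) > 1:
                inhibitables.append(name[:-1])
                colroles[i] = ("inhibitor", name[:-1])
            else:
                stimuli.append(name)
                colroles[i] = ("stimulus", name)
        elif col.startswith("DA:"):
            colroles[i] = ("time", col[3:])
        elif col.startswith("DV:"):
            readouts.append(col[3:])
            colroles[i] = ("value", col[3:])
        else:
            colroles[i] = ("ignore", col)
    da_names = {n for (k, n) in colroles.values() if k == "time"}
    if "ALL" not in da_names:
        for r in readouts:
            if r not in da_names:
                raise FormatError(f"DV:{r} column has no matching DA:{r} column")
    return colroles, stimuli, inhibitables, readouts


def read_midas(path):
    """Read a MIDAS CSV.

    Returns ``(datasets, roles)`` where ``datasets`` maps each acquisition
    time to a :class:`Dataset` (conditions in first-appearance order) and
    ``roles`` carries the stimuli / inhibitables / readouts declared by the
    header prefixes.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        colroles, stimuli, inhibitables, readouts = _parse_midas_header(header)
        roles = Roles.of(stimuli, inhibitables, readouts)

        cond_order: list = []  # Condition in first-appearance order
        cond_index: dict = {}
        per_time: dict = {}  # time -> {cond_idx: {readout: value}}
        for lineno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            stim_on, inh_on = set(), set()
            times, values = {}, {}
            for i, cell in enumerate(row):
                kind, name = colroles.get(i, ("ignore", ""))
                cell = cell.strip()
                if kind in ("stimulus", "inhibitor"):
                    try:
                        v = float(cell) if cell else 0.0
                    except ValueError:
                        raise FormatError(f"{path}:{lineno}: non-numeric TR cell {cell!r}") from None
                    if v not in (0.0, 1.0):
                        raise FormatError(f"{path}:{lineno}: TR:{name} must be 0 or 1, got {cell}")
                    if v == 1.0:
                        (stim_on if kind == "stimulus" else inh_on).add(name)
                elif kind == "time":
                    if cell:
                        try:
                            times[name] = float(cell)
                        except ValueError:
                            raise FormatError(f"{path}:{lineno}: non-numeric DA cell {cell!r}") from None
                elif kind == "value":
                    if cell == "" or cell.upper() in ("NA", "NAN"):
                        values[name] = math.nan
                    else:
                        try:
                            values[name] = float(cell)
                        except ValueError:
                            raise FormatError(f"{path}:{lineno}: non-numeric DV cell {cell!r}") from None
            if not times:
                raise FormatError(f"{path}:{lineno}: row has no acquisition time")
            tvals = set(times.values())
            if len(tvals) > 1:
                raise FormatError(f"{path}:{lineno}: acquisition times differ within a row: {sorted(tvals)}")
            t = tvals.pop()
            cond = Condition.of(stim_on, inh_on)
            if cond not in cond_index:
                cond_index[cond] = len(cond_order)
                cond_order.append(cond)
            per_time.setdefault(t, {})[cond_index[cond]] = values

    datasets = {}
    for t, rows in sorted(per_time.items()):
        vals = np.full((len(cond_order), len(readouts)), np.nan)
        for ci, rowvals in rows.items():
            for j, r in enumerate(readouts):
                if r in rowvals:
                    vals[ci, j] = rowvals[r]
        datasets[t] = Dataset(list(cond_order), list(readouts), vals, time=t)
    return datasets, roles


def write_midas(dataset: Dataset, roles: Roles, path) -> None:
    """Write a single-time Dataset as a MIDAS CSV (round-trips through read_midas)."""
    stimuli = sorted(roles.stimuli)
    inhibitables = sorted(roles.inhibitables)
    readouts = list(dataset.readouts)
    header = (
        [f"TR:{s}" for s in stimuli]
        + [f"TR:{n}i" for n in inhibitables]
        + [f"DA:{r}" for r in readouts]
        + [f"DV:{r}" for r in readouts]
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for cond, row in zip(dataset.conditions, dataset.values):
            cells = [str(int(s in cond.stimulus_on)) for s in stimuli]
            cells += [str(int(n in cond.inhibitor_on)) for n in inhibitables]
            cells += [repr(dataset.time) for _ in readouts]
            cells += ["" if np.isnan(v) else repr(float(v)) for v in row]
            writer.writerow(cells)


def select_time(datasets: Mapping[float, Dataset], t: Optional[float] = None) -> Dataset:
    """Pick the Dataset at time ``t``; default is the earliest strictly positive time.

    Quasi-steady-state predictions approximate the cell state shortly after a
    perturbation, so the default acquisition time is the earliest one after
    stimulation (t = 0 holds the pre-stimulation baseline).
    """
    times = sorted(datasets)
    if t is None:
        positive = [x for x in times if x > 0]
        if not positive:
            raise ValueError(f"no strictly positive acquisition time among {times}")
        return datasets[positive[0]]
    if t not in datasets:
        raise ValueError(f"time {t} not available; acquisition times: {times}")
    return datasets[t]


def normalize(dataset: Dataset, mode: str = "minmax") -> Dataset:
    """Scale each readout column to [0, 1].

    ``minmax``: per-column linear min-max scaling over non-missing entries;
    a constant column maps to all zeros. ``passthrough``: values must already
    lie in [0, 1] and are returned unchanged.
    """
    vals = dataset.values.copy()
    if mode == "passthrough":
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("passthrough normalization requires values in [0, 1]")
        return dataset.copy_with(values=vals)
    if mode != "minmax":
        raise ValueError(f"unknown normalization mode {mode!r}")
    for j in range(vals.shape[1]):
        col = vals[:, j]
        finite = col[~np.isnan(col)]
        if not finite.size:
            continue
        lo, hi = finite.min(), finite.max()
        if hi > lo:
            vals[:, j] = (col - lo) / (hi - lo)
        else:
            vals[:, j] = np.where(np.isnan(col), np.nan, 0.0)
    return dataset.copy_with(values=vals)


def discretize_scaled(value: float, precision_digits: int) -> int:
    """Round a [0,1] value onto the integer grid 0..10**precision_digits.

    Ties round half away from zero (0.005 at 2 digits -> 1 on the grid,
    i.e. 0.01). The integer grid is what exact scoring operates on.
    """
    if precision_digits < 0:
        raise ValueError("precision_digits must be >= 0")
    if math.isnan(value):
        raise ValueError("cannot discretize a missing value")
    if not 0 <= value <= 1:
        raise ValueError(f"discretize expects a value in [0, 1], got {value}")
    q = Decimal(repr(float(value))).scaleb(precision_digits)
    return int(q.to_integral_value(rounding=ROUND_HALF_UP))


def discretize(value: float, precision_digits: int):
    """Round ``value`` to the nearest multiple of 10**(-precision_digits).

    Missing (NaN) stays missing; ties round half away from zero. Idempotent.
    """
    if isinstance(value, float) and math.isnan(value):
        return value
    return discretize_scaled(value, precision_digits) / (10 ** precision_digits)
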