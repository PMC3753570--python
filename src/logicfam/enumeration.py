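"""Global lexicographic optimization and complete enumeration of the model family.

The learning problem is discrete: minimize MSE first, then model size, over
all 2^|E| subsets of the candidate hyperedges. The point of the method is a
*completeness guarantee* — not just one optimum but every model within a
stated tolerance of it, so that the family itself can be analyzed. The
native backend here is a complete, exact scan of the search space: models
are evaluated in bit-parallel numpy batches with exact integer scoring, so
optimality, ties and tolerance thresholds are decided without rounding.
Suboptimal models are those with MSE <= (1 + eps) * MSE_opt (multiplicative
tolerance, exact rational arithmetic) and size below an absolute bound,
which defaults to the optimal size.

The scan is exhaustive by construction, which bounds the tractable |E|
(configurable, default 26 ~ 6.7e7 models). Larger instances require an
external complete solver backend, which is an extension point, not bundled.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from fractions import Fraction
from math import floor
from typing import Optional, Union

import numpy as np

from . import _engine
from .hypergraph import ExpandedHypergraph
from .model import LogicModel, Score
from .types import Dataset

__all__ = [
    "EnumerationConfig",
    "ModelFamily",
    "optimize",
    "enumerate_family",
    "family_mse_spectrum",
    "write_family_csv",
    "read_family_csv",
    "write_family_metadata",
]


class FamilyTooLarge(RuntimeError):
    """The tolerance admits more models than the configured safety cap."""


@dataclass(frozen=True)
class EnumerationConfig:
    """Tolerances and numerics for family enumeration.

    ``fit_tolerance`` is the fraction eps: members satisfy
    MSE <= (1 + eps) * MSE_opt. ``size_bound`` is an absolute cap on model
    size, or ``"optimal"`` to use the optimal size. ``precision`` is the
    discretization grid in digits.
    """

    fit_tolerance: float = 0.0
    size_bound: Union[int, str] = "optimal"
    precision: int = 2
    backend: str = "native"
    max_steps: Optional[int] = None
    safety_cap: int = 1_000_000
    max_search_bits: int = 26
    chunk_bits: int = 20

    def __post_init__(self):
        if self.fit_tolerance < 0:
            raise ValueError("fit_tolerance must be >= 0")
        if self.size_bound != "optimal" and int(self.size_bound) < 0:
            raise ValueError("size_bound must be >= 0 or 'optimal'")
        if self.backend not in ("native", "external-solver"):
            raise ValueError(f"unknown backend {self.backend!r}")

    @property
    def tolerance_fraction(self) -> Fraction:
        # via the decimal literal so 0.1 means exactly 1/10
        return Fraction(repr(float(self.fit_tolerance)))


@dataclass
class ModelFamily:
    """All models within tolerance, with exact scores, in canonical order."""

    hypergraph: ExpandedHypergraph
    models: list  # of LogicModel
    scores: list  # of Score, parallel to models
    mse_opt: Fraction
    size_opt: int
    config: EnumerationConfig

    def __len__(self):
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    @property
    def masks(self) -> np.ndarray:
        return np.array([m.mask for m in self.models], dtype=np.int64)

    def presence_matrix(self) -> np.ndarray:
        """(n_models, n_hyperedges) 0/1 matrix of gate membership."""
        e = self.hypergraph.n_hyperedges
        masks = self.masks
        cols = [((masks >> g) & 1).astype(np.int8) for g in range(e)]
        return np.stack(cols, axis=1) if cols else np.zeros((len(self.models), 0), np.int8)

    @property
    def optimal_models(self) -> list:
        return [
            m
            for m, s in zip(self.models, self.scores)
            if s.mse == self.mse_opt and s.size == self.size_opt
        ]


def _bitrev_key(mask: int, nbits: int) -> int:
    # lexicographic order on bit-vectors (bit 0 first) == ascending reversed-bit integer
    out = 0
    for i in range(nbits):
        out |= ((mask >> i) & 1) << (nbits - 1 - i)
    return out


def _check_instance(hg: ExpandedHypergraph, dataset: Dataset, config: EnumerationConfig):
    if hg.n_hyperedges == 0:
        raise ValueError("hypergraph has no hyperedges; nothing to optimize")
    if dataset.n_conditions == 0:
        raise ValueError("dataset has no conditions")
    if config.backend == "external-solver":
        raise NotImplementedError(
            "the external-solver backend is an extension point; no complete external "
            "solver is bundled — use backend='native'"
        )
    if hg.n_hyperedges > config.max_search_bits:
        raise ValueError(
            f"instance has {hg.n_hyperedges} hyperedges; the native complete scan is "
            f"capped at {config.max_search_bits} (2^{config.max_search_bits} models)"
        )


def _chunks(n_models: int, chunk_bits: int):
    chunk = 1 << chunk_bits
    for start in range(0, n_models, chunk):
        yield np.arange(start, min(start + chunk, n_models), dtype=np.int64)


def optimize(hg: ExpandedHypergraph, dataset: Dataset, precision: int = 2,
             max_steps: Optional[int] = None,
             config: Optional[EnumerationConfig] = None):
    """Exact global lexicographic optimum of (MSE, size).

    Returns ``(mse_opt, size_opt, witness)`` where the witness is the first
    optimal model in canonical bit-vector order.
    """
    config = config or EnumerationConfig(precision=precision, max_steps=max_steps)
    _check_instance(hg, dataset, config)
    e = hg.n_hyperedges
    best = None  # (sse, size, bitrev_key, mask)
    n_compared = None
    for masks in _chunks(1 << e, config.chunk_bits):
        sse, size, n_compared = _engine.batch_scores(
            hg, dataset, masks, precision=config.precision, max_steps=config.max_steps
        )
        order = np.lexsort((size, sse))
        top = order[0]
        cand_sse, cand_size = int(sse[top]), int(size[top])
        ties = masks[(sse == cand_sse) & (size == cand_size)]
        key = min(_bitrev_key(int(m), e) for m in ties)
        mask = next(int(m) for m in ties if _bitrev_key(int(m), e) == key)
        cand = (cand_sse, cand_size, key, mask)
        if best is None or cand[:3] < best[:3]:
            best = cand
    sse_opt, size_opt, _, mask = best
    mse_opt = Fraction(sse_opt, n_compared * 10 ** (2 * config.precision))
    return mse_opt, size_opt, LogicModel(mask, hg)


def enumerate_family(hg: ExpandedHypergraph, dataset: Dataset,
                     config: Optional[EnumerationConfig] = None) -> ModelFamily:
    """Enumerate EVERY model within the configured tolerances.

    Membership: MSE <= (1 + eps) * MSE_opt (exact rational comparison) and
    size <= size_bound (``"optimal"`` resolves to the optimal size). Models
    are returned deduplicated in canonical bit-vector order.
    """
    config = config or EnumerationConfig()
    _check_instance(hg, dataset, config)
    e = hg.n_hyperedges
    scale2 = 10 ** (2 * config.precision)

    mse_opt, size_opt, _ = optimize(hg, dataset, config=config)
    eps = config.tolerance_fraction
    # sse is integer, so sse <= (1+eps)*sse_opt  <=>  sse <= floor((1+eps)*sse_opt)
    n_compared_total = int(np.sum(~np.isnan(dataset.values)))
    sse_opt_scaled = mse_opt * n_compared_total * scale2
    sse_max = floor((1 + eps) * sse_opt_scaled)
    size_max = size_opt if config.size_bound == "optimal" else int(config.size_bound)

    kept_masks: list = []
    kept_scores: list = []
    for masks in _chunks(1 << e, config.chunk_bits):
        sse, size, n_compared = _engine.batch_scores(
            hg, dataset, masks, precision=config.precision, max_steps=config.max_steps
        )
        ok = (sse <= sse_max) & (size <= size_max)
        if np.any(ok):
            kept_masks.extend(int(m) for m in masks[ok])
            kept_scores.extend(
                Score(int(a), n_compared, int(b), config.precision)
                for a, b in zip(sse[ok], size[ok])
            )
        if len(kept_masks) > config.safety_cap:
            raise FamilyTooLarge(
                f"family exceeds the safety cap of {config.safety_cap} models; "
                f"tighten fit_tolerance or size_bound"
            )
    order = sorted(range(len(kept_masks)), key=lambda i: _bitrev_key(kept_masks[i], e))
    models = [LogicModel(kept_masks[i], hg) for i in order]
    scores = [kept_scores[i] for i in order]
    return ModelFamily(hg, models, scores, mse_opt, size_opt, config)


def family_mse_spectrum(family: ModelFamily):
    """Distinct exact MSE values in the family, ascending, with model counts."""
    if not family.models:
        raise ValueError("family is empty")
    counts: dict = {}
    for s in family.scores:
        counts[s.mse] = counts.get(s.mse, 0) + 1
    return [(mse, counts[mse]) for mse in sorted(counts)]


def write_family_csv(family: ModelFamily, path) -> None:
    e = family.hypergraph.n_hyperedges
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow([f"e{i}" for i in range(e)]
                        + ["sse_scaled", "n_compared", "size", "precision", "mse"])
        for m, s in zip(family.models, family.scores):
            writer.writerow(
                list(m.bitvector())
                + [s.sse_scaled, s.n_compared, s.size, s.precision, repr(float(s.mse))]
            )


def read_family_csv(path, hg: ExpandedHypergraph,
                    config: Optional[EnumerationConfig] = None) -> ModelFamily:
    e = hg.n_hyperedges
    models, scores = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        expected = {f"e{i}" for i in range(e)} | {"sse_scaled", "n_compared", "size", "precision"}
        missing = expected - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"family file is missing columns: {sorted(missing)}")
        for row in reader:
            mask = sum(int(row[f"e{i}"]) << i for i in range(e))
            models.append(LogicModel(mask, hg))
            scores.append(
                Score(int(row["sse_scaled"]), int(row["n_compared"]),
                      int(row["size"]), int(row["precision"]))
            )
    if not models:
        raise ValueError(f"{path}: empty family file")
    mse_opt = min(s.mse for s in scores)
    size_opt = min(s.size for s in scores if s.mse == mse_opt)
    return ModelFamily(hg, models, scores, mse_opt, size_opt, config or EnumerationConfig())


def write_family_metadata(family: ModelFamily, path) -> None:
    spectrum = family_mse_spectrum(family)
    meta = {
        "n_models": len(family),
        "n_hyperedges": family.hypergraph.n_hyperedges,
        "mse_opt": float(family.mse_opt),
        "mse_opt_exact": [family.mse_opt.numerator, family.mse_opt.denominator],
        "size_opt": family.size_opt,
        "n_optimal_models": len(family.optimal_models),
        "fit_tolerance": family.config.fit_tolerance,
        "size_bound": family.config.size_bound,
        "precision": family.config.precision,
        "backend": family.config.backend,
        "n_distinct_mse": len(spectrum),
        "mse_spectrum": [[float(m), c] for m, c in spectrum],
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
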