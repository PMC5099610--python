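"""Three-dimensional clone pooling, PCR screening and deconvolution.

A clone at address (plate p, row r, column c) is a member of exactly three
superpools: plate pool p, row pool r and column pool c.  A marker screen
calls each pool positive or negative; intersecting the positive index sets
of the three dimensions yields candidate clone addresses.  When each
dimension has exactly one positive pool the candidate is unambiguous and is
confirmed directly; any ambiguity is resolved by a follow-up round of
per-clone confirmation PCR, for which an ordered test plan is produced.

Pools are modeled as presence/absence: a pool is truly positive iff at
least one member clone's insert fully contains the marker amplicon.
Observed calls apply independent per-pool false-negative / false-positive
flips.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import MarkerLocus
from .physmap import BacClone

__all__ = [
    "PoolDesign",
    "PoolSet",
    "ScreenResult",
    "DeconvolutionResult",
    "build_pools",
    "screen_marker",
    "deconvolve",
    "confirmation_plan",
    "run_confirmation",
    "DuplicateAddressError",
    "InconsistentScreenWarning",
]

Address = tuple[int, int, int]


class DuplicateAddressError(ValueError):
    pass


class InconsistentScreenWarning(UserWarning):
    """Some dimensions positive but their intersection is empty.

    Mirrors real screens where a marker amplifies in pools but no clone
    coordinate can be established.
    """


@dataclass(frozen=True)
class PoolDesign:
    n_plates: int = 100
    n_rows: int = 16
    n_cols: int = 24

    def __post_init__(self):
        if min(self.n_plates, self.n_rows, self.n_cols) < 1:
            raise ValueError("all pool dimensions must be >= 1")

    @property
    def n_pools(self) -> int:
        return self.n_plates + self.n_rows + self.n_cols

    @property
    def n_addresses(self) -> int:
        return self.n_plates * self.n_rows * self.n_cols


@dataclass
class PoolSet:
    design: PoolDesign
    clones: dict[Address, BacClone]  # occupied addresses

    def members(self, dim: str, index: int) -> list[BacClone]:
        axis = {"plate": 0, "row": 1, "col": 2}[dim]
        return [c for a, c in self.clones.items() if a[axis] == index]

    def membership_frame(self) -> pd.DataFrame:
        rows = []
        for (p, r, c), clone in sorted(self.clones.items()):
            rows.append((clone.clone_id, "plate", p))
            rows.append((clone.clone_id, "row", r))
            rows.append((clone.clone_id, "col", c))
        return pd.DataFrame(rows, columns=["clone_id", "dimension", "index"])


@dataclass
class ScreenResult:
    marker_id: str
    positive_plates: set[int] = field(default_factory=set)
    positive_rows: set[int] = field(default_factory=set)
    positive_cols: set[int] = field(default_factory=set)
    fn_rate: float = 0.0
    fp_rate: float = 0.0


@dataclass
class DeconvolutionResult:
    marker_id: str
    confirmed: set[Address] = field(default_factory=set)
    candidates: set[Address] = field(default_factory=set)
    confirmations_needed: list[Address] = field(default_factory=list)


def build_pools(clones: list[BacClone], design: PoolDesign) -> PoolSet:
    """Assign clones to their plate/row/column pools.

    Every clone lands in exactly three pools; duplicate addresses raise
    :class:`DuplicateAddressError`.
    """
    occupied: dict[Address, BacClone] = {}
    for c in clones:
        p, r, col = c.address
        if not (0 <= p < design.n_plates and 0 <= r < design.n_rows and 0 <= col < design.n_cols):
            raise ValueError(f"address {c.address} outside design {design}")
        if c.address in occupied:
            raise DuplicateAddressError(f"address {c.address} assigned twice")
        occupied[c.address] = c
    return PoolSet(design, occupied)


def screen_marker(
    marker: MarkerLocus,
    pools: PoolSet,
    fn_rate: float = 0.0,
    fp_rate: float = 0.0,
    seed: int = 0,
) -> ScreenResult:
    """Simulate one round of 3D-pool PCR screening for a marker.

    A pool is truly positive iff >= 1 member clone fully contains the marker
    amplicon; each pool's observed call then flips with the false-negative
    (positive pools) or false-positive (negative pools) rate.
    """
    if not (0 <= fn_rate < 1 and 0 <= fp_rate < 1):
        raise ValueError("noise rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    amp_start = marker.position_bp
    amp_end = marker.position_bp + len(marker.amplicon)
    true_pos: list[set[int]] = [set(), set(), set()]
    for addr, clone in pools.clones.items():
        if clone.contains(amp_start, amp_end):
            for axis in range(3):
                true_pos[axis].add(addr[axis])
    sizes = (pools.design.n_plates, pools.design.n_rows, pools.design.n_cols)
    observed: list[set[int]] = []
    for axis, n in enumerate(sizes):
        calls = set()
        for idx in range(n):
            if idx in true_pos[axis]:
                if rng.random() >= fn_rate:
                    calls.add(idx)
            elif fp_rate > 0 and rng.random() < fp_rate:
                calls.add(idx)
        observed.append(calls)
    return ScreenResult(marker.marker_id, *observed, fn_rate=fn_rate, fp_rate=fp_rate)


def deconvolve(result: ScreenResult, pools: PoolSet) -> DeconvolutionResult:
    """Intersect positive pool indices back to candidate clone addresses.

    Candidates are the Cartesian product of the three positive index sets
    intersected with occupied library addresses.  A unique candidate (all
    dimensions singleton) is confirmed outright; otherwise every candidate
    goes to the confirmation list.  Inconsistent screens (some dimension
    positive, empty product) emit :class:`InconsistentScreenWarning` and an
    empty result.
    """
    dims = (result.positive_plates, result.positive_rows, result.positive_cols)
    if any(dims) and not all(dims):
        warnings.warn(
            f"marker {result.marker_id}: positive calls in some dimensions only",
            InconsistentScreenWarning,
            stacklevel=2,
        )
        return DeconvolutionResult(result.marker_id)
    if not any(dims):
        return DeconvolutionResult(result.marker_id)
    product = {
        (p, r, c)
        for p in sorted(dims[0])
        for r in sorted(dims[1])
        for c in sorted(dims[2])
    }
    candidates = {a for a in product if a in pools.clones}
    if not candidates:
        warnings.warn(
            f"marker {result.marker_id}: no occupied address in positive product",
            InconsistentScreenWarning,
            stacklevel=2,
        )
        return DeconvolutionResult(result.marker_id)
    if all(len(d) == 1 for d in dims) and len(candidates) == 1:
        return DeconvolutionResult(result.marker_id, confirmed=set(candidates))
    plan = confirmation_plan(candidates)
    return DeconvolutionResult(result.marker_id, candidates=candidates, confirmations_needed=plan)


def confirmation_plan(candidates: set[Address]) -> list[Address]:
    """Order candidate addresses for confirmation PCR.

    Addresses sharing pools with many other candidates are tested first:
    their outcome constrains the most remaining plate/row/column
    combinations.  Ties break on (plate, row, col) for determinism.
    """
    cands = sorted(candidates)

    def ambiguity(addr: Address) -> int:
        return sum(
            sum(1 for o in cands if o != addr and o[axis] == addr[axis])
            for axis in range(3)
        )

    return sorted(cands, key=lambda a: (-ambiguity(a), a))


def run_confirmation(
    result: DeconvolutionResult,
    is_positive,
) -> tuple[set[Address], int]:
    """Execute the confirmation plan with pool-coverage inference.

    ``is_positive(addr) -> bool`` is the confirmation PCR (assumed
    error-free).  Each positive pool of the first-round screen must contain
    at least one truly positive clone, so when all but one candidate of a
    pool have tested negative the remaining one is inferred positive without
    a reaction.  Returns the confirmed positive set and the number of
    reactions actually run.
    """
    confirmed = set(result.confirmed)
    if not result.confirmations_needed:
        return confirmed, 0
    unknown = set(result.confirmations_needed)
    negatives: set[Address] = set()
    n_tests = 0

    def infer() -> None:
        changed = True
        while changed:
            changed = False
            for axis in range(3):
                pools_idx = {a[axis] for a in unknown | confirmed}
                for idx in pools_idx:
                    members = [a for a in unknown if a[axis] == idx]
                    has_pos = any(a[axis] == idx for a in confirmed)
                    if not has_pos and len(members) == 1:
                        confirmed.add(members[0])
                        unknown.discard(members[0])
                        changed = True

    for addr in result.confirmations_needed:
        if addr not in unknown:
            continue
        infer()
        if addr not in unknown:
            continue
        n_tests += 1
        unknown.discard(addr)
        if is_positive(addr):
            confirmed.add(addr)
        else:
            negatives.add(addr)
    infer()
    return confirmed, n_tests


def screen_frame(results: list[ScreenResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for dim, idxs in (
            ("plate", r.positive_plates),
            ("row", r.positive_rows),
            ("col", r.positive_cols),
        ):
            for i in sorted(idxs):
                rows.append((r.marker_id, dim, i))
    return pd.DataFrame(rows, columns=["marker_id", "dimension", "index"])


def deconvolution_frame(results: list[DeconvolutionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for a in sorted(r.confirmed):
            rows.append((r.marker_id, *a, "confirmed"))
        for a in sorted(r.candidates):
            rows.append((r.marker_id, *a, "candidate"))
    return pd.DataFrame(rows, columns=["marker_id", "plate", "row", "col", "status"])
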