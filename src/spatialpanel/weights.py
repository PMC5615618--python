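"""Contiguity spatial weight matrices.

Builds binary Rook-contiguity matrices from printed adjacency lists
(region number, region name, neighbour codes), row-standardizes them,
and exposes the eigenvalue spectrum that the spatial likelihoods and
the admissible interval for the spatial parameters are built from.

The packaged China fixture encodes the 31 provincial-level regions with
the island patch applied in the data itself: Hainan, which shares no
land boundary, lists Guangdong as its single neighbour.  Islands in
*other* inputs are treated as errors, not silently patched — whether to
connect an island is a data decision, not an algorithm.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "AdjacencyList",
    "SpatialWeights",
    "AdjacencyParseError",
    "AdjacencyValidationError",
    "IslandError",
    "parse_adjacency_table",
    "china_adjacency",
    "build_binary_weights",
    "row_standardize",
    "weights_spectrum",
    "china_weights",
    "write_gal",
    "read_gal",
]


class AdjacencyParseError(ValueError):
    """Malformed adjacency input (duplicate codes, unknown neighbours, bad GAL)."""


class AdjacencyValidationError(ValueError):
    """Structurally invalid adjacency (asymmetric pairs, self-loops)."""


class IslandError(ValueError):
    """A region with no neighbours where the operation requires none."""


@dataclass(frozen=True)
class AdjacencyList:
    """Region registry with neighbour codes.

    Parameters
    ----------
    regions
        Ordered ``(region_number, region_name)`` pairs.
    neighbors
        Map from region number to the set of neighbouring region numbers.
    """

    regions: tuple[tuple[int, str], ...]
    neighbors: Mapping[int, frozenset[int]]

    @property
    def n(self) -> int:
        return len(self.regions)

    @property
    def region_numbers(self) -> list[int]:
        return [num for num, _ in self.regions]

    @property
    def region_names(self) -> dict[int, str]:
        return {num: name for num, name in self.regions}

    def validate(self) -> None:
        numbers = self.region_numbers
        known = set(numbers)
        if len(known) != len(numbers):
            raise AdjacencyParseError("duplicate region numbers")
        for i, nbrs in self.neighbors.items():
            if i in nbrs:
                raise AdjacencyValidationError(f"region {i} lists itself as a neighbour")
            for j in nbrs:
                if j not in known:
                    raise AdjacencyParseError(
                        f"region {i} references unknown neighbour code {j}"
                    )
                if i not in self.neighbors[j]:
                    raise AdjacencyValidationError(
                        f"asymmetric adjacency: {i} lists {j} but {j} does not list {i}"
                    )


@dataclass
class SpatialWeights:
    """An n x n contiguity weight matrix.

    ``style`` is ``"binary"`` (0/1, symmetric) or ``"row_standardized"``
    (each row divided by its row sum, so spatial lags are neighbour
    averages).  ``region_order`` fixes the row/column order; all matrices
    derived from the China fixture use numeric order 1..31 so they are
    comparable across runs.  ``spectrum`` caches the eigenvalues of the
    row-standardized matrix.
    """

    matrix: np.ndarray
    style: str
    region_order: list[int]
    names: dict[int, str] = field(default_factory=dict)
    spectrum: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def index_of(self, region_number: int) -> int:
        return self.region_order.index(region_number)


def parse_adjacency_table(source) -> AdjacencyList:
    """Parse a printed adjacency table into a validated :class:`AdjacencyList`.

    Each record carries a region number, a region name, and a
    whitespace-separated list of neighbour codes (possibly empty).
    Lines starting with ``#`` and blank lines are ignored.

    Raises
    ------
    AdjacencyParseError
        Duplicate region numbers or neighbour codes that reference an
        unknown region.
    AdjacencyValidationError
        A pair of regions whose adjacency is not symmetric (both regions
        are named in the message).
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    regions: list[tuple[int, str]] = []
    neighbors: dict[int, frozenset[int]] = {}
    seen: set[int] = set()
    for raw in source:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise AdjacencyParseError(f"record too short: {line!r}")
        try:
            num = int(parts[0])
        except ValueError as exc:
            raise AdjacencyParseError(f"bad region number in {line!r}") from exc
        if num <= 0:
            raise AdjacencyParseError(f"region number must be positive: {num}")
        if num in seen:
            raise AdjacencyParseError(f"duplicate region number {num}")
        seen.add(num)
        name = parts[1]
        try:
            codes = frozenset(int(c) for c in parts[2:])
        except ValueError as exc:
            raise AdjacencyParseError(f"bad neighbour code in {line!r}") from exc
        regions.append((num, name))
        neighbors[num] = codes
    if not regions:
        raise AdjacencyParseError("empty adjacency table")
    adj = AdjacencyList(regions=tuple(regions), neighbors=neighbors)
    adj.validate()
    return adj


def china_adjacency() -> AdjacencyList:
    """The packaged 31-region China Rook-contiguity table."""
    text = (
        resources.files("spatialpanel.data")
        .joinpath("china_adjacency.txt")
        .read_text(encoding="utf-8")
    )
    return parse_adjacency_table(text)


def build_binary_weights(adj: AdjacencyList) -> SpatialWeights:
    """Binary contiguity matrix: entry (i, j) is 1 iff j neighbours i.

    Raises :class:`IslandError` for any region with an empty neighbour
    set — an island makes the matrix non-row-standardizable, and the
    packaged fixture has none by construction.
    """
    adj.validate()
    order = adj.region_numbers
    pos = {num: k for k, num in enumerate(order)}
    n = len(order)
    W = np.zeros((n, n))
    for i, nbrs in adj.neighbors.items():
        if not nbrs:
            raise IslandError(f"region {i} ({adj.region_names[i]}) has no neighbours")
        for j in nbrs:
            W[pos[i], pos[j]] = 1.0
    return SpatialWeights(matrix=W, style="binary", region_order=list(order),
                          names=adj.region_names)


def row_standardize(W: SpatialWeights) -> SpatialWeights:
    """Divide each row by its row sum (style becomes ``row_standardized``)."""
    if W.style != "binary":
        raise ValueError("row_standardize expects a binary-style matrix")
    sums = W.matrix.sum(axis=1)
    if np.any(sums == 0):
        idx = int(np.argmin(sums))
        raise IslandError(f"region {W.region_order[idx]} has zero row sum")
    out = W.matrix / sums[:, None]
    return SpatialWeights(matrix=out, style="row_standardized",
                          region_order=list(W.region_order), names=dict(W.names))


def weights_spectrum(W: SpatialWeights, imag_tol: float = 1e-8) -> np.ndarray:
    """Eigenvalues of the row-standardized matrix, sorted ascending.

    A row-standardized matrix built from a symmetric binary base is
    similar to a symmetric matrix (D^{1/2} W D^{-1/2} with D the degree
    matrix), so its spectrum is real and bounded by 1.  The interval
    ``(1/min(spectrum), 1)`` is the admissible range for the spatial
    autoregressive parameters.  The result is cached on ``W.spectrum``.
    """
    if W.style != "row_standardized":
        raise ValueError("spectrum is defined for the row-standardized matrix")
    if W.spectrum is not None:
        return W.spectrum
    vals = np.linalg.eigvals(W.matrix)
    if np.max(np.abs(vals.imag)) > imag_tol:
        raise ArithmeticError(
            "complex eigenvalues: the binary base matrix is not symmetric"
        )
    spec = np.sort(vals.real)
    W.spectrum = spec
    return spec


def china_weights(style: str = "row_standardized") -> SpatialWeights:
    """Convenience: the China fixture as a ready weight matrix."""
    W = build_binary_weights(china_adjacency())
    if style == "binary":
        return W
    if style == "row_standardized":
        return row_standardize(W)
    raise ValueError(f"unknown style {style!r}")


def write_gal(adj: AdjacencyList | SpatialWeights) -> str:
    """Serialize adjacency to the GAL contiguity interchange format.

    Header line is the region count; then, per region, a line with the
    region id and its neighbour count followed by a line of neighbour ids.
    """
    if isinstance(adj, SpatialWeights):
        order = adj.region_order
        pos = {num: k for k, num in enumerate(order)}
        neighbors = {
            i: frozenset(order[j] for j in np.nonzero(adj.matrix[pos[i]])[0])
            for i in order
        }
    else:
        order = adj.region_numbers
        neighbors = adj.neighbors
    if not order:
        raise AdjacencyParseError("empty region set")
    lines = [str(len(order))]
    for i in order:
        nbrs = sorted(neighbors[i])
        lines.append(f"{i} {len(nbrs)}")
        lines.append(" ".join(str(j) for j in nbrs))
    return "\n".join(lines) + "\n"


def read_gal(text: str) -> AdjacencyList:
    """Parse a GAL file back into an :class:`AdjacencyList`.

    Region names are not carried by GAL; they are synthesized as
    ``"r<id>"``.
    """
    tokens = text.split()
    if not tokens:
        raise AdjacencyParseError("empty GAL input")
    try:
        n = int(tokens[0])
    except ValueError as exc:
        raise AdjacencyParseError("malformed GAL header") from exc
    k = 1
    regions: list[tuple[int, str]] = []
    neighbors: dict[int, frozenset[int]] = {}
    for _ in range(n):
        if k + 1 > len(tokens):
            raise AdjacencyParseError("GAL truncated before region record")
        rid, cnt = int(tokens[k]), int(tokens[k + 1])
        k += 2
        if k + cnt > len(tokens):
            raise AdjacencyParseError(f"GAL neighbour count mismatch for region {rid}")
        nbrs = frozenset(int(t) for t in tokens[k:k + cnt])
        if len(nbrs) != cnt:
            raise AdjacencyParseError(f"duplicate neighbours for region {rid}")
        k += cnt
        regions.append((rid, f"r{rid}"))
        neighbors[rid] = nbrs
    if k != len(tokens):
        raise AdjacencyParseError("trailing tokens after GAL body")
    adj = AdjacencyList(regions=tuple(regions), neighbors=neighbors)
    adj.validate()
    return adj
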