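"""Lattice state, periodic von Neumann neighborhoods and initial states.

Players occupy an L x L square lattice with periodic boundary conditions
(a torus).  Sites are addressed 0-based, row-major.  Each site interacts
with its four orthogonal neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import GameVariant, Strategy, get_variant

__all__ = [
    "LatticeState",
    "InitialStateSpec",
    "neighbors",
    "neighbor_table",
    "init_state",
    "state_to_text",
    "state_from_text",
    "save_png",
]

MIN_L = 4  # below this the four neighbors are not distinct


@dataclass
class LatticeState:
    """L x L periodic grid of variant-local strategy indices.

    ``grid[i, j]`` holds the index of the strategy in
    ``variant.strategies`` occupying site (i, j).
    """

    variant: GameVariant
    grid: np.ndarray

    def __post_init__(self) -> None:
        g = np.ascontiguousarray(self.grid, dtype=np.int8)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError(f"grid must be square, got shape {g.shape}")
        if g.shape[0] < MIN_L:
            raise ValueError(f"lattice side must be >= {MIN_L}, got {g.shape[0]}")
        if g.min(initial=0) < 0 or g.max(initial=0) >= self.variant.n_strategies:
            raise ValueError("grid contains codes outside the variant's strategy set")
        self.grid = g

    @property
    def L(self) -> int:
        return self.grid.shape[0]

    def counts(self) -> np.ndarray:
        """Site count per variant strategy (length n_strategies, sums to L^2)."""
        return np.bincount(self.grid.ravel(), minlength=self.variant.n_strategies)

    def fractions(self) -> np.ndarray:
        return self.counts() / self.grid.size

    def strategies_present(self) -> set[Strategy]:
        return {self.variant.strategies[i] for i in np.unique(self.grid)}

    def copy(self) -> "LatticeState":
        return LatticeState(self.variant, self.grid.copy())


def neighbors(site: tuple[int, int], L: int) -> tuple[tuple[int, int], ...]:
    """Four von Neumann neighbors of ``site`` with periodic wrap.

    Order is fixed (up, down, left, right) for reproducibility.
    """
    r, c = site
    if not (0 <= r < L and 0 <= c < L):
        raise IndexError(f"site {site} out of range for L={L}")
    return ((r - 1) % L, c), ((r + 1) % L, c), (r, (c - 1) % L), (r, (c + 1) % L)


def neighbor_table(L: int) -> np.ndarray:
    """Flat-index neighbor table of shape (L*L, 4), order up/down/left/right.

    Row ``k`` lists the flat indices of the neighbors of site
    ``(k // L, k % L)``; used by the simulation kernels.
    """
    idx = np.arange(L * L).reshape(L, L)
    up = np.roll(idx, 1, axis=0)
    down = np.roll(idx, -1, axis=0)
    left = np.roll(idx, 1, axis=1)
    right = np.roll(idx, -1, axis=1)
    return np.stack(
        [up.ravel(), down.ravel(), left.ravel(), right.ravel()], axis=1
    ).astype(np.int64)


@dataclass
class InitialStateSpec:
    """How to populate the initial lattice.

    mode
        ``uniform_random`` -- independent uniform draw over the variant's
        strategies at each site (the default protocol);
        ``weighted_random`` -- independent draw with per-strategy
        ``weights``;
        ``blocks`` -- vertical stripes in the order given by ``layout``,
        each a ``(strategy, width_fraction)`` pair (prepared initial
        states for interface experiments).
    """

    mode: str = "uniform_random"
    weights: dict[Strategy, float] | None = None
    layout: tuple[tuple[Strategy, float], ...] | None = None

    _MODES = ("uniform_random", "weighted_random", "blocks")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}, got {self.mode!r}")
        if self.mode == "weighted_random":
            if not self.weights:
                raise ValueError("weighted_random requires weights")
            vals = list(self.weights.values())
            if any(w < 0 for w in vals):
                raise ValueError("weights must be nonnegative")
            if not np.isclose(sum(vals), 1.0):
                raise ValueError("weights must sum to 1")
        if self.mode == "blocks":
            if not self.layout:
                raise ValueError("blocks mode requires a layout")
            if not np.isclose(sum(f for _, f in self.layout), 1.0):
                raise ValueError("stripe width fractions must sum to 1")


def _check_strategies(strats, variant: GameVariant) -> None:
    for s in strats:
        if s not in variant:
            raise ValueError(f"strategy {s.name} not in variant {variant.name!r}")


def init_state(
    spec: InitialStateSpec,
    variant: str | GameVariant,
    L: int,
    seed: int | np.random.Generator | None = None,
) -> LatticeState:
    """Generate an initial lattice state; deterministic given ``seed``."""
    variant = get_variant(variant)
    if L < MIN_L:
        raise ValueError(f"L must be >= {MIN_L}, got {L}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = variant.n_strategies
    if spec.mode == "uniform_random":
        grid = rng.integers(0, n, size=(L, L), dtype=np.int8)
    elif spec.mode == "weighted_random":
        _check_strategies(spec.weights, variant)
        p = np.zeros(n)
        for s, w in spec.weights.items():
            p[variant.index[s]] = w
        p = p / p.sum()
        grid = rng.choice(n, size=(L, L), p=p).astype(np.int8)
    else:  # blocks: vertical stripes, widths rounded cumulatively
        _check_strategies((s for s, _ in spec.layout), variant)
        grid = np.empty((L, L), dtype=np.int8)
        edges = np.round(np.cumsum([0.0] + [f for _, f in spec.layout]) * L).astype(int)
        edges[-1] = L
        for (s, _), lo, hi in zip(spec.layout, edges[:-1], edges[1:]):
            grid[:, lo:hi] = variant.index[s]
    return LatticeState(variant, grid)


def stripes_CLM() -> InitialStateSpec:
    """Equal-width L | M | C vertical stripes: the prepared initial state
    used for the minimal interface model."""
    return InitialStateSpec(
        mode="blocks",
        layout=(
            (Strategy.L, 1 / 3),
            (Strategy.M, 1 / 3),
            (Strategy.C, 1 / 3),
        ),
    )


def half_blocks(a: Strategy, b: Strategy) -> InitialStateSpec:
    """Two half-lattice vertical blocks, used for pairwise invasion runs."""
    return InitialStateSpec(mode="blocks", layout=((a, 0.5), (b, 0.5)))


def state_to_text(state: LatticeState) -> str:
    """One character per site (strategy label), one row per line."""
    labels = [s.name for s in state.variant.strategies]
    return "\n".join("".join(labels[c] for c in row) for row in state.grid) + "\n"


def state_from_text(text: str, variant: str | GameVariant) -> LatticeState:
    variant = get_variant(variant)
    lut = {s.name: i for s, i in variant.index.items()}
    rows = [r for r in text.strip().splitlines()]
    grid = np.array([[lut[ch] for ch in row] for row in rows], dtype=np.int8)
    return LatticeState(variant, grid)


#: Snapshot colors (RGB), following the convention red = C, light blue = L,
#: dark blue = M; O is white and the full-rank punishers H/P are green.
STRATEGY_COLORS = {
    Strategy.O: (245, 245, 245),
    Strategy.C: (214, 39, 40),
    Strategy.L: (120, 190, 255),
    Strategy.M: (20, 60, 160),
    Strategy.H: (44, 160, 44),
    Strategy.P: (44, 160, 44),
}


def save_png(
    state: LatticeState, path, scale: int = 2, metadata: dict[str, str] | None = None
) -> None:
    """Write a PNG raster of the lattice, one colored pixel block per site.

    ``metadata`` entries are embedded as PNG text chunks (used to stamp
    figures with the run-manifest hash).
    """
    from PIL import Image
    from PIL.PngImagePlugin import PngInfo

    palette = np.array(
        [STRATEGY_COLORS[s] for s in state.variant.strategies], dtype=np.uint8
    )
    img = palette[state.grid]
    if scale > 1:
        img = np.kron(img, np.ones((scale, scale, 1), dtype=np.uint8))
    info = PngInfo()
    for k, v in (metadata or {}).items():
        info.add_text(k, v)
    Image.fromarray(img, mode="RGB").save(path, pnginfo=info)
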