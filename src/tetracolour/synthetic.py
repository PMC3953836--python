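"""Synthetic fixtures: toy visual systems, spectra, Yule trees, and
planted-convergence datasets.

Every generator is a pure function of the configuration (including its
seed), so fixtures are reproducible bit-for-bit. The planted-convergence
dataset provides positive and negative controls for the convergence test:
with ``convergence_pull = 0`` it is pure Brownian motion against a FIXED
target region (so the test's p-value is calibrated); with a positive pull,
the pendant branches of ``n_planted`` designated tips are blended toward
the target centre, planting detectable entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import EllipsoidRegion
from .phylo import Phylogeny, PhyloNode, RateMatrix, TraitMatrix
from .spectra import WAVELENGTH_GRID, ReflectanceSpectrum
from .visual import VisualSystem

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "make_toy_visual_system",
    "make_spectra",
    "make_illuminant",
    "yule_tree",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for all synthetic generators. Defaults give a mid-sized,
    well-behaved dataset."""

    seed: int = 0
    n_species: int = 50
    receptor_centers: tuple[float, ...] = (350.0, 450.0, 550.0, 650.0)
    receptor_width: float = 40.0
    tree_birth_rate: float = 1.0
    bm_rate: RateMatrix = field(default_factory=lambda: RateMatrix.isotropic(1.0))
    convergence_pull: float = 0.0
    n_planted: int = 0
    target_center: tuple[float, float, float] = (2.5, 0.0, 0.0)
    target_radius: float = 0.8
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if len(self.receptor_centers) != 4:
            raise ValueError("need exactly 4 receptor centers")
        if len(set(self.receptor_centers)) != 4:
            raise ValueError("receptor centers must be distinct")
        if any(not (300.0 <= c <= 700.0) for c in self.receptor_centers):
            raise ValueError("receptor centers must lie in [300, 700] nm")
        if tuple(sorted(self.receptor_centers)) != tuple(self.receptor_centers):
            raise ValueError("receptor centers must be ascending (short -> long)")
        if self.receptor_width <= 0:
            raise ValueError("receptor width must be positive")
        if not (0.0 <= self.convergence_pull <= 1.0):
            raise ValueError("convergence_pull must be in [0, 1]")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.tree_birth_rate <= 0:
            raise ValueError("birth rate must be positive")
        if self.target_radius <= 0:
            raise ValueError("target radius must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def make_toy_visual_system(cfg: SyntheticConfig) -> VisualSystem:
    """Gaussian receptor curves at the configured centres, truncated to
    zero beyond four widths (so each receptor has a genuinely exclusive
    spectral window)."""
    curves = []
    for i, c in enumerate(cfg.receptor_centers, start=1):
        r = np.exp(-0.5 * ((WAVELENGTH_GRID - c) / cfg.receptor_width) ** 2)
        r[np.abs(WAVELENGTH_GRID - c) > 4.0 * cfg.receptor_width] = 0.0
        curves.append(ReflectanceSpectrum(WAVELENGTH_GRID, r, f"receptor{i}_{int(c)}nm"))
    return VisualSystem(name="toy", sensitivities=tuple(curves))


def make_illuminant(cfg: SyntheticConfig) -> ReflectanceSpectrum:
    """Flat unit illuminant on the standard grid."""
    return ReflectanceSpectrum(
        WAVELENGTH_GRID, np.ones_like(WAVELENGTH_GRID), "flat_illuminant"
    )


def _logistic(wl: np.ndarray, midpoint: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(wl - midpoint) / scale))


def make_spectra(cfg: SyntheticConfig) -> list[ReflectanceSpectrum]:
    """A labelled batch of synthetic reflectance spectra on the standard
    grid.

    Always includes: ``flat`` (constant 0.5), ``red_step`` (long-wavelength
    logistic step, the reddest spectrum in the batch), and
    ``leaf_background`` (mid-wavelength green bump). The remaining
    ``n_species`` spectra are seeded random mixtures of logistic steps and
    Gaussian bumps with additive noise of sd ``noise_sd`` (clipped at 0).
    """
    rng = np.random.default_rng(cfg.seed)
    wl = WAVELENGTH_GRID
    out = [
        ReflectanceSpectrum(wl, np.full(wl.shape, 0.5), "flat"),
        ReflectanceSpectrum(
            wl, 0.03 + 0.9 * _logistic(wl, 625.0, 12.0), "red_step"
        ),
        ReflectanceSpectrum(
            wl,
            0.05 + 0.12 * np.exp(-0.5 * ((wl - 550.0) / 45.0) ** 2),
            "leaf_background",
        ),
    ]
    for i in range(cfg.n_species):
        base = 0.05 + 0.05 * rng.random()
        r = np.full(wl.shape, base)
        for _ in range(rng.integers(1, 4)):
            kind = rng.random()
            if kind < 0.5:
                amp = rng.uniform(0.1, 0.5)
                centre = rng.uniform(320.0, 660.0)
                width = rng.uniform(25.0, 80.0)
                r = r + amp * np.exp(-0.5 * ((wl - centre) / width) ** 2)
            else:
                amp = rng.uniform(0.1, 0.4)
                mid = rng.uniform(350.0, 600.0)
                r = r + amp * _logistic(wl, mid, rng.uniform(8.0, 30.0))
        r = r + rng.normal(0.0, cfg.noise_sd, size=wl.shape)
        out.append(ReflectanceSpectrum(wl, np.maximum(r, 0.0), f"synthetic_{i:03d}"))
    return out


def yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int | np.random.Generator = 0
) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` tips, rescaled to unit depth.

    Lineages split at exponential waiting times; after the last split an
    extra exponential interval gives the pendant edges positive length.
    Tips are labelled ``t1..tn`` in preorder.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = PhyloNode()
    birth_time: dict[int, float] = {}
    active = []
    t = 0.0
    for _ in range(2):  # crown tree: the root splits at time zero
        child = PhyloNode()
        root.add_child(child)
        birth_time[id(child)] = 0.0
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        j = int(rng.integers(len(active)))
        node = active.pop(j)
        node.length = (
            t - birth_time[id(node)] if node.parent is not None else None
        )
        birth_time[id(node)] = t  # split time, reused for children
        for _ in range(2):
            child = PhyloNode()
            node.add_child(child)
            birth_time[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    for node in active:
        node.length = t_end - birth_time[id(node)]

    # unit-depth rescale; label tips in a traversal-stable order
    def scale(node: PhyloNode) -> None:
        if node.length is not None:
            node.length /= t_end
        for c in node.children:
            scale(c)

    scale(root)
    counter = [0]

    def label(node: PhyloNode) -> None:
        if not node.children:
            counter[0] += 1
            node.name = f"t{counter[0]}"
        for c in node.children:
            label(c)

    label(root)
    return Phylogeny(root)


@dataclass(frozen=True)
class SyntheticDataset:
    tree: Phylogeny
    tips: TraitMatrix
    true_states: TraitMatrix  # all nodes, as simulated
    region: EllipsoidRegion
    planted: tuple[str, ...]
    truth: int  # planted entry count, scored on the true states


def simulate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Yule tree + (possibly biased) Brownian-motion traits + a fixed
    spherical target region.

    The region is determined by the config alone (centre
    ``cfg.target_center``, radius ``cfg.target_radius``), never by the
    data, so that with ``convergence_pull = 0`` the convergence test is a
    genuine null experiment. With a positive pull, the pendant branch of
    each of ``n_planted`` randomly designated tips is displaced as
    ``(1 - pull) * BM step + pull * (centre - parent state)``.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = yule_tree(cfg.n_species, cfg.tree_birth_rate, rng)
    n_tips = len(tree.tips)
    if cfg.n_planted > n_tips:
        raise ValueError(f"n_planted={cfg.n_planted} exceeds tip count {n_tips}")

    planted: tuple[str, ...] = ()
    if cfg.n_planted > 0:
        labels = np.array(tree.tip_labels)
        planted = tuple(
            sorted(rng.choice(labels, size=cfg.n_planted, replace=False).tolist())
        )
    planted_set = set(planted)
    center = np.asarray(cfg.target_center, dtype=float)

    L = cfg.bm_rate.factor()
    states = np.empty((len(tree.nodes), 3))
    states[0] = 0.0
    for node in tree.nodes[1:]:
        parent = states[node.parent.index]
        step = np.sqrt(node.length) * (L @ rng.standard_normal(3))
        if node.is_tip and node.name in planted_set and cfg.convergence_pull > 0:
            states[node.index] = (
                parent
                + (1.0 - cfg.convergence_pull) * step
                + cfg.convergence_pull * (center - parent)
            )
        else:
            states[node.index] = parent + step

    region = EllipsoidRegion(
        center=center,
        shape=np.eye(3),
        radius=cfg.target_radius,
        label="synthetic_target",
    )
    inside = region.contains_points(states)
    truth = 0
    for node in tree.nodes[1:]:
        if (
            node.is_tip
            and node.name in planted_set
            and inside[node.index]
            and not inside[node.parent.index]
        ):
            truth += 1

    names = [n.name for n in tree.nodes]
    true_states = TraitMatrix.from_arrays(names, states)
    tips = TraitMatrix(
        {n.name: states[n.index] for n in tree.tips}
    )
    return SyntheticDataset(
        tree=tree,
        tips=tips,
        true_states=true_states,
        region=region,
        planted=planted,
        truth=truth,
    )
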