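"""Seeded generators for datasets with the statistical structure of the
method's use cases, so kernels and the filter are testable offline.

Expression is simulated directly on the log scale with Gaussian noise — the
simplest model satisfying the method's assumptions (the filter itself is
distribution-agnostic). A negative-binomial count mode is available behind a
flag for realism. Technical artifacts of real scRNA-seq (dropout, batch
effects, library-size variation) are deliberately not modelled.

Scenarios
---------
* ``two_signal_dataset`` — every cell carries two independent categorical
  attributes ("color" to be filtered, "shape" hidden underneath).
* ``subclone_dataset`` — a cycling base population plus a subclone created by
  doubling the expression of a random gene subset on the linear scale.
* ``spatial_local_dataset`` — a lattice of cells with a smooth local spatial
  field plus a sparse global subpopulation scattered across the tissue.
* ``case_control_dataset`` — cases and controls share a latent manifold; a
  responder fraction of cases carries an added response program.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import ExpressionMatrix


@dataclass
class SyntheticTruth:
    """Ground-truth annotations attached to a generated dataset."""

    filtered_signal_label: np.ndarray  # the nuisance signal ("color")
    hidden_signal_label: np.ndarray  # the hidden signal ("shape")
    responder_flag: Optional[np.ndarray] = None
    spatial_coords: Optional[np.ndarray] = None
    seed: Optional[int] = None
    extras: dict = field(default_factory=dict)


def _ids(n: int, g: int) -> tuple[list[str], list[str]]:
    return [f"cell_{i}" for i in range(n)], [f"gene_{j}" for j in range(g)]


def _maybe_counts(X_log: np.ndarray, rng: np.random.Generator,
                  counts: bool, nb_dispersion: float = 0.5) -> np.ndarray:
    """Optionally replace the log-scale matrix by log1p of NB counts with the
    same log-scale mean structure."""
    if not counts:
        return X_log
    mu = np.expm1(np.clip(X_log, a_min=None, a_max=20.0))
    mu = np.maximum(mu, 1e-8)
    r = 1.0 / nb_dispersion
    p = r / (r + mu)
    draws = rng.negative_binomial(r, p)
    return np.log1p(draws.astype(np.float64))


def two_signal_dataset(
    n_cells: int = 600,
    n_genes: int = 200,
    n_color_classes: int = 3,
    n_shape_classes: int = 3,
    effect_color: float = 1.0,
    effect_shape: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    counts: bool = False,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two independent overlaid categorical signals per cell.

    Disjoint gene blocks: the first 20% of genes carry the color signal, the
    next 20% the shape signal, the rest are background. Each class gets a
    fixed archetype over its block (constant within class), so filtering with
    the true color one-hot kernel centers the color block exactly at zero
    noise.
    """
    rng = np.random.default_rng(seed)
    block = n_genes // 5
    if 2 * block > n_genes:
        raise ValueError("gene blocks exceed n_genes")
    color = rng.integers(0, n_color_classes, size=n_cells)
    shape = rng.integers(0, n_shape_classes, size=n_cells)

    color_arch = rng.normal(0.0, effect_color, size=(n_color_classes, block))
    shape_arch = rng.normal(0.0, effect_shape, size=(n_shape_classes, block))

    X = np.zeros((n_cells, n_genes))
    X[:, :block] += color_arch[color] if effect_color > 0 else 0.0
    X[:, block:2 * block] += shape_arch[shape] if effect_shape > 0 else 0.0
    X += rng.normal(0.0, noise_sd, size=X.shape) if noise_sd > 0 else 0.0
    X = _maybe_counts(X, rng, counts)

    cells, genes = _ids(n_cells, n_genes)
    truth = SyntheticTruth(
        filtered_signal_label=np.array([f"c{c}" for c in color]),
        hidden_signal_label=np.array([f"s{s}" for s in shape]),
        seed=seed,
        extras={
            "color_genes": genes[:block],
            "shape_genes": genes[block:2 * block],
        },
    )
    return ExpressionMatrix(X, cells, genes), truth


def cycling_base(
    n_cells: int = 279,
    n_genes: int = 300,
    frac_cc_genes: float = 0.3,
    amplitude: float = 1.0,
    noise_sd: float = 0.3,
    n_phases: int = 3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Base population with a cyclic cell-cycle covariate.

    Each cell gets an angle theta on the unit circle and a discrete phase
    label (equal angular sectors). Cell-cycle genes follow
    amplitude * cos(theta + offset_g) on the log scale; the rest is baseline.
    """
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, size=n_cells)
    phase = np.floor(theta / (2 * np.pi / n_phases)).astype(int)
    n_cc = int(round(frac_cc_genes * n_genes))
    offsets = rng.uniform(0, 2 * np.pi, size=n_cc)
    baseline = rng.normal(2.0, 0.2, size=n_genes)

    X = np.tile(baseline, (n_cells, 1))
    X[:, :n_cc] += amplitude * np.cos(theta[:, None] + offsets[None, :])
    X += rng.normal(0.0, noise_sd, size=X.shape)

    cells, genes = _ids(n_cells, n_genes)
    truth = SyntheticTruth(
        filtered_signal_label=np.array([f"phase_{p}" for p in phase]),
        hidden_signal_label=np.zeros(n_cells, dtype=int),
        seed=seed,
        extras={"theta": theta, "cc_genes": genes[:n_cc], "n_cc": n_cc},
    )
    return ExpressionMatrix(X, cells, genes), truth


def subclone_dataset(
    base: Optional[tuple[ExpressionMatrix, SyntheticTruth]] = None,
    frac_cells: float = 0.4,
    n_doubled_genes: int = 60,
    frac_cc_genes: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Create a subclone by doubling a random gene subset in a cell fraction.

    Doubling happens on the linear scale (expm1 -> x2 -> log1p). The doubled
    gene set mixes cycle-related and unrelated genes per ``frac_cc_genes``.
    Truth records the clone flag (as hidden signal), the cycle phase (as the
    signal to filter) and the doubled gene list.
    """
    rng = np.random.default_rng(seed)
    if base is None:
        base = cycling_base(seed=seed)
    X0, truth0 = base
    n_cells, n_genes = X0.values.shape
    if n_doubled_genes > n_genes:
        raise ValueError("n_doubled_genes exceeds the number of genes")

    n_clone = int(round(frac_cells * n_cells))
    clone_cells = rng.choice(n_cells, size=n_clone, replace=False)
    n_cc_avail = truth0.extras.get("n_cc", 0)
    n_from_cc = min(int(round(frac_cc_genes * n_doubled_genes)), n_cc_avail)
    cc_pick = rng.choice(n_cc_avail, size=n_from_cc, replace=False) if n_from_cc else np.array([], dtype=int)
    other_pool = np.arange(n_cc_avail, n_genes)
    other_pick = rng.choice(other_pool, size=n_doubled_genes - n_from_cc, replace=False)
    doubled = np.sort(np.concatenate([cc_pick, other_pick]))

    X = X0.values.copy()
    if n_clone:
        lin = np.expm1(X[np.ix_(clone_cells, doubled)])
        X[np.ix_(clone_cells, doubled)] = np.log1p(2.0 * lin)

    clone_flag = np.zeros(n_cells, dtype=bool)
    clone_flag[clone_cells] = True
    truth = SyntheticTruth(
        filtered_signal_label=truth0.filtered_signal_label,
        hidden_signal_label=np.where(clone_flag, "clone", "intact"),
        seed=seed,
        extras={
            **truth0.extras,
            "doubled_genes": [X0.feature_ids[j] for j in doubled],
            "clone_flag": clone_flag,
        },
    )
    return ExpressionMatrix(X, list(X0.cell_ids), list(X0.feature_ids)), truth


def spatial_local_dataset(
    grid_w: int = 20,
    grid_h: int = 20,
    n_genes: int = 150,
    local_lengthscale: float = 4.0,
    field_amplitude: float = 1.5,
    n_global_pop: int = 40,
    global_effect: float = 1.0,
    noise_sd: float = 0.3,
    n_bumps: int = 6,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Lattice of cells: smooth spatial field + sparse global subpopulation.

    The local field is a mixture of Gaussian bumps over the lattice driving
    the first half of the genes (the signal a spatial-distance kernel should
    remove). ``n_global_pop`` cells scattered uniformly across the tissue get
    an added program on a disjoint gene block (the hidden signal).
    ``local_lengthscale=0`` disables the field entirely.
    """
    rng = np.random.default_rng(seed)
    xs, ys = np.meshgrid(np.arange(grid_w), np.arange(grid_h))
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    n_cells = coords.shape[0]
    if n_global_pop >= n_cells:
        raise ValueError("n_global_pop must be smaller than the lattice size")

    half = n_genes // 2
    field = np.zeros(n_cells)
    if local_lengthscale > 0:
        centers = rng.uniform([0, 0], [grid_w, grid_h], size=(n_bumps, 2))
        signs = rng.choice([-1.0, 1.0], size=n_bumps)
        for c, s in zip(centers, signs):
            d2 = ((coords - c) ** 2).sum(axis=1)
            field += s * np.exp(-d2 / (2 * local_lengthscale**2))
        field *= field_amplitude
    gene_loading = rng.normal(1.0, 0.2, size=half)

    X = np.zeros((n_cells, n_genes))
    X[:, :half] = field[:, None] * gene_loading[None, :]

    global_cells = rng.choice(n_cells, size=n_global_pop, replace=False)
    program = rng.normal(global_effect, 0.2, size=n_genes - half)
    X[np.ix_(global_cells, np.arange(half, n_genes))] += program[None, :]
    X += rng.normal(0.0, noise_sd, size=X.shape)

    flag = np.zeros(n_cells, dtype=bool)
    flag[global_cells] = True
    cells, genes = _ids(n_cells, n_genes)
    truth = SyntheticTruth(
        filtered_signal_label=np.digitize(field, np.quantile(field, [0.25, 0.5, 0.75])),
        hidden_signal_label=np.where(flag, "global", "local"),
        spatial_coords=coords,
        seed=seed,
        extras={"field": field, "global_flag": flag,
                "field_genes": genes[:half], "program_genes": genes[half:]},
    )
    return ExpressionMatrix(X, cells, genes), truth


def case_control_dataset(
    n_case: int = 300,
    n_control: int = 300,
    n_genes: int = 200,
    frac_responders: float = 0.25,
    response_effect: float = 1.0,
    shared_structure_dim: int = 5,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Case-control design with a responder subpopulation.

    Cases and controls share a latent manifold (random low-rank structure); a
    ``frac_responders`` fraction of case cells additionally expresses a
    response program on the last quarter of the genes. Controls come first in
    the returned matrix, then cases; truth carries group labels and the
    responder flag (controls are always False).
    """
    rng = np.random.default_rng(seed)
    n_cells = n_case + n_control
    W = rng.normal(0.0, 1.0, size=(shared_structure_dim, n_genes))
    Z = rng.normal(0.0, 1.0, size=(n_cells, shared_structure_dim))
    X = Z @ W / np.sqrt(shared_structure_dim)

    group = np.array(["control"] * n_control + ["case"] * n_case)
    responders = np.zeros(n_cells, dtype=bool)
    n_resp = int(round(frac_responders * n_case))
    if n_resp and response_effect != 0:
        resp_cells = n_control + rng.choice(n_case, size=n_resp, replace=False)
        responders[resp_cells] = True
        block = np.arange(n_genes - n_genes // 4, n_genes)
        program = rng.normal(response_effect, 0.2, size=block.size)
        X[np.ix_(resp_cells, block)] += program[None, :]
    elif n_resp:
        resp_cells = n_control + rng.choice(n_case, size=n_resp, replace=False)
        responders[resp_cells] = True
    X += rng.normal(0.0, noise_sd, size=X.shape)

    cells, genes = _ids(n_cells, n_genes)
    truth = SyntheticTruth(
        filtered_signal_label=group,
        hidden_signal_label=np.where(responders, "responder", "non_responder"),
        responder_flag=responders,
        seed=seed,
        extras={
            "latent": Z,
            "case_mask": group == "case",
            "control_mask": group == "control",
            "response_genes": genes[n_genes - n_genes // 4:],
        },
    )
    return ExpressionMatrix(X, cells, genes), truth
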