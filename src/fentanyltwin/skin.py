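"""One-dimensional drug transport through a transdermal patch and skin layers.

The patch and each skin layer are treated as homogeneous slabs in which the
drug moves by Fickian diffusion.  At layer interfaces the drug partitions:
the concentration jumps by the ratio of the layers' partition coefficients.
Following the standard reformulation, each layer is assigned a *drug
capacity* ``K_i`` and the solver works with the *drug potential*
``psi = c_i / K_i``, which is continuous across every interface.  The
governing equation in each layer is the capacity-weighted diffusion equation

    K_i dpsi/dt = d/dz ( D_i K_i dpsi/dz )

with a zero-flux condition at the outer patch surface and a Dirichlet
condition at the dermis base, where the potential tracks the plasma
concentration supplied by the pharmacokinetic model (a pure-sink condition is
available as a configuration switch).

Space is discretized by a cell-centred finite-volume scheme on a grid with
geometric refinement toward the layer interfaces; time integration is left to
the caller (see :mod:`fentanyltwin.engine`) or to :func:`solve_transport` for
stand-alone transport problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import InvalidParameterError, SolverFailureError
from .units import FLUX_SI_TO_UG_CM2_H, HOUR_S

__all__ = [
    "LayerSpec",
    "PatchSpec",
    "SkinStack",
    "Grid1D",
    "TransportState",
    "FluxSeries",
    "derive_partition",
    "lag_time",
    "equivalent_dermis_length",
    "dermis_diffusivity",
    "solve_transport",
    "DEFAULT_DERMIS_DIFFUSIVITY",
]

#: Constant dermis diffusivity (m^2 s^-1) used when no Arrhenius constants
#: for the temperature dependence are supplied.
DEFAULT_DERMIS_DIFFUSIVITY = 3.82e-11

GAS_CONSTANT = 8.314462618  # J mol^-1 K^-1


@dataclass(frozen=True)
class LayerSpec:
    """Geometry and transport properties of one homogeneous slab.

    Parameters
    ----------
    name:
        Label ("patch", "stratum_corneum", ...).
    thickness_m:
        Slab thickness d (m), > 0.
    diffusivity_m2_s:
        Drug diffusion coefficient D (m^2 s^-1), > 0.
    capacity:
        Dimensionless drug capacity K; the local concentration is
        ``c = K * psi``.
    """

    name: str
    thickness_m: float
    diffusivity_m2_s: float
    capacity: float

    def __post_init__(self) -> None:
        if self.thickness_m <= 0:
            raise InvalidParameterError(f"layer {self.name!r}: thickness must be > 0")
        if self.diffusivity_m2_s <= 0:
            raise InvalidParameterError(f"layer {self.name!r}: diffusivity must be > 0")
        if self.capacity <= 0:
            raise InvalidParameterError(f"layer {self.name!r}: capacity must be > 0")


@dataclass(frozen=True)
class PatchSpec:
    """A drug-in-matrix transdermal patch.

    The initial drug concentration is uniform and equals
    ``drug_mass_kg / (area_m2 * layer.thickness_m)``.
    """

    layer: LayerSpec
    area_m2: float
    drug_mass_kg: float
    nominal_flux_ug_h: float | None = None  # label metadata only

    def __post_init__(self) -> None:
        if self.area_m2 <= 0:
            raise InvalidParameterError("patch area must be > 0")
        if self.drug_mass_kg < 0:
            raise InvalidParameterError("patch drug mass must be >= 0")

    @property
    def initial_concentration_kg_m3(self) -> float:
        return self.drug_mass_kg / (self.area_m2 * self.layer.thickness_m)


@dataclass(frozen=True)
class SkinStack:
    """Ordered stack of slabs: patch on top, then skin layers down to the
    dermis base where the blood boundary sits."""

    patch: PatchSpec
    skin_layers: tuple[LayerSpec, ...]

    def __post_init__(self) -> None:
        if not self.skin_layers:
            raise InvalidParameterError("stack needs at least one skin layer")

    @property
    def layers(self) -> tuple[LayerSpec, ...]:
        return (self.patch.layer,) + self.skin_layers

    def interface_partitions(self) -> dict[str, float]:
        """Partition coefficient ``K_{i/j} = K_i / K_j`` at every interface."""
        return derive_partition(self)


def derive_partition(stack: SkinStack) -> dict[str, float]:
    """Interface partition coefficients of a stack.

    For adjacent layers i (upstream) and j (downstream),
    ``K_{i/j} = K_i / K_j``, so the upstream/downstream concentration ratio
    at the interface equals this coefficient.
    """
    out: dict[str, float] = {}
    layers = stack.layers
    for up, dn in zip(layers[:-1], layers[1:]):
        if up.capacity <= 0 or dn.capacity <= 0:
            raise InvalidParameterError("capacities must be positive")
        out[f"{up.name}/{dn.name}"] = up.capacity / dn.capacity
    return out


def lag_time(thickness_m: float, diffusivity_m2_s: float) -> float:
    """Asymptotic diffusion lag time of a slab: ``t_D = d^2 / (6 D)`` (s)."""
    if thickness_m < 0:
        raise InvalidParameterError("thickness must be >= 0")
    if diffusivity_m2_s <= 0:
        raise InvalidParameterError("diffusivity must be > 0")
    return thickness_m**2 / (6.0 * diffusivity_m2_s)


def equivalent_dermis_length(
    total_lag_s: float, epidermis_lag_s: float, dermis_diffusivity_m2_s: float
) -> float:
    """Equivalent diffusive dermis thickness from the residual lag time.

    The dermis in vivo combines diffusion and capillary advection; the model
    replaces it by a reduced purely-diffusive thickness chosen so that the
    lag remaining after the epidermis' contribution is reproduced:
    ``d = sqrt(6 D (t_total - t_epidermis))``.
    """
    if epidermis_lag_s < 0:
        raise InvalidParameterError("epidermis lag must be >= 0")
    if total_lag_s < epidermis_lag_s:
        raise InvalidParameterError("total lag must be >= epidermis lag")
    if dermis_diffusivity_m2_s <= 0:
        raise InvalidParameterError("diffusivity must be > 0")
    return math.sqrt(6.0 * dermis_diffusivity_m2_s * (total_lag_s - epidermis_lag_s))


def dermis_diffusivity(
    temperature_K: float = 310.5,
    constants: dict[str, float] | None = None,
) -> float:
    """Dermis diffusion coefficient, optionally temperature dependent.

    When ``constants`` supplies the full set ``{D0, E, D306, DT}`` the
    Arrhenius-plus-offset form ``D0 * exp(-E / (R T)) + 400 (DT - D306)`` is
    evaluated.  Without constants the fixed literature value
    :data:`DEFAULT_DERMIS_DIFFUSIVITY` is returned; a partial constant set is
    rejected.
    """
    if constants is None:
        return DEFAULT_DERMIS_DIFFUSIVITY
    required = {"D0", "E", "D306", "DT"}
    missing = required - constants.keys()
    if missing:
        raise InvalidParameterError(
            f"temperature-dependent dermis diffusivity needs all of {sorted(required)}; "
            f"missing {sorted(missing)}"
        )
    return constants["D0"] * math.exp(
        -constants["E"] / (GAS_CONSTANT * temperature_K)
    ) + 400.0 * (constants["DT"] - constants["D306"])


def _layer_edges(thickness: float, n: int, ratio: float) -> np.ndarray:
    """Cell edges in [0, thickness] geometrically refined toward both faces."""
    half = n // 2
    w = ratio ** np.arange(half)
    if n % 2 == 0:
        w = np.concatenate([w, w[::-1]])
    else:
        w = np.concatenate([w, [w[-1] * ratio], w[::-1]])
    return np.concatenate([[0.0], np.cumsum(w / w.sum() * thickness)])


@dataclass(frozen=True)
class Grid1D:
    """Finite-volume grid over a stack of slabs.

    Every layer interface coincides with a cell face; cells are clustered
    geometrically toward the interfaces, where concentration gradients are
    steepest.  ``cell_widths``, ``diffusivity`` and ``capacity`` are
    flattened over all layers, top (patch surface) to bottom (dermis base).
    """

    cell_widths: np.ndarray
    diffusivity: np.ndarray
    capacity: np.ndarray
    layer_cells: tuple[int, ...]
    layer_names: tuple[str, ...]

    @classmethod
    def build(
        cls,
        stack: SkinStack,
        cells_per_layer: Sequence[int] = (30, 20, 20, 40),
        refine_ratio: float = 1.3,
    ) -> "Grid1D":
        layers = stack.layers
        if len(cells_per_layer) != len(layers):
            raise InvalidParameterError(
                f"cells_per_layer has {len(cells_per_layer)} entries for "
                f"{len(layers)} layers"
            )
        if any(n < 2 for n in cells_per_layer):
            raise InvalidParameterError("need at least 2 cells per layer")
        dz, D, K = [], [], []
        for lay, n in zip(layers, cells_per_layer):
            edges = _layer_edges(lay.thickness_m, int(n), refine_ratio)
            dz.append(np.diff(edges))
            D.append(np.full(int(n), lay.diffusivity_m2_s))
            K.append(np.full(int(n), lay.capacity))
        return cls(
            cell_widths=np.concatenate(dz),
            diffusivity=np.concatenate(D),
            capacity=np.concatenate(K),
            layer_cells=tuple(int(n) for n in cells_per_layer),
            layer_names=tuple(lay.name for lay in layers),
        )

    @property
    def n_cells(self) -> int:
        return self.cell_widths.size

    @property
    def n_patch_cells(self) -> int:
        return self.layer_cells[0]

    def cell_centers(self) -> np.ndarray:
        edges = np.concatenate([[0.0], np.cumsum(self.cell_widths)])
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class TransportState:
    """Drug potential on the grid at one instant (capacity-normalized
    concentration, kg m^-3 units)."""

    time_s: float
    psi: np.ndarray

    def concentration(self, grid: Grid1D) -> np.ndarray:
        """Local concentration ``c = K * psi`` per cell."""
        return grid.capacity[-self.psi.size:] * self.psi


@dataclass
class FluxSeries:
    """Boundary fluxes of a transport solution, in field units."""

    time_h: np.ndarray
    flux_patch_ug_cm2_h: np.ndarray   # out of the patch into the stratum corneum
    flux_dermis_ug_cm2_h: np.ndarray  # out of the dermis into the blood


class TransportOperator:
    """Discrete diffusion operator for one application site.

    Precomputes face resistances for the full (patch + skin) layout and for
    the skin-only layout used after patch removal.  The flux between adjacent
    cells a, b is ``(psi_a - psi_b) / R`` with the series resistance
    ``R = (dz_a/2)/(D_a K_a) + (dz_b/2)/(D_b K_b)``; this realizes both
    Fick's law inside layers and the partition condition at interfaces.
    """

    def __init__(self, grid: Grid1D, bottom_dirichlet: bool = True):
        self.grid = grid
        self.bottom_dirichlet = bottom_dirichlet
        self._layouts: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
        for n in (grid.n_cells, grid.n_cells - grid.n_patch_cells):
            dz = grid.cell_widths[-n:]
            DK = (grid.diffusivity * grid.capacity)[-n:]
            half = 0.5 * dz
            r_face = half[:-1] / DK[:-1] + half[1:] / DK[1:]
            inv_cap = 1.0 / (grid.capacity[-n:] * dz)
            self._layouts[n] = (r_face, inv_cap, half[-1] / DK[-1])

    def rhs(self, psi: np.ndarray, cp_si: float, out: np.ndarray) -> float:
        """dpsi/dt for one site; returns the flux into blood (kg m^-2 s^-1).

        ``cp_si`` is the plasma concentration imposed at the dermis base
        (ignored in pure-sink mode, where the base potential is 0).
        """
        n = psi.size
        r_face, inv_cap, r_bot = self._layouts[n]
        q = np.empty(n + 1)
        q[0] = 0.0
        np.divide(psi[:-1] - psi[1:], r_face, out=q[1:-1])
        bottom = cp_si if self.bottom_dirichlet else 0.0
        q[-1] = (psi[-1] - bottom) / r_bot
        np.multiply(q[:-1] - q[1:], inv_cap, out=out)
        return q[-1]

    def patch_outflux(self, psi: np.ndarray) -> float:
        """Flux across the patch/skin interface (kg m^-2 s^-1); 0 when the
        patch has been removed."""
        n = psi.size
        if n != self.grid.n_cells:
            return 0.0
        r_face, _, _ = self._layouts[n]
        i = self.grid.n_patch_cells
        return (psi[i - 1] - psi[i]) / r_face[i - 1]

    def blood_flux(self, psi: np.ndarray, cp_si: float) -> float:
        n = psi.size
        _, _, r_bot = self._layouts[n]
        bottom = cp_si if self.bottom_dirichlet else 0.0
        return (psi[-1] - bottom) / r_bot

    def patch_mass(self, psi: np.ndarray, area_m2: float) -> float:
        """Drug mass in the patch (kg); 0 after removal."""
        if psi.size != self.grid.n_cells:
            return 0.0
        npt = self.grid.n_patch_cells
        seg = slice(0, npt)
        return float(
            np.sum(self.grid.capacity[seg] * psi[seg] * self.grid.cell_widths[seg])
            * area_m2
        )

    def skin_mass(self, psi: np.ndarray, area_m2: float) -> float:
        """Drug mass stored in the skin layers (kg)."""
        nskin = self.grid.n_cells - self.grid.n_patch_cells
        seg_psi = psi[-nskin:]
        K = self.grid.capacity[-nskin:]
        dz = self.grid.cell_widths[-nskin:]
        return float(np.sum(K * seg_psi * dz) * area_m2)


def solve_transport(
    stack: SkinStack,
    grid: Grid1D | None = None,
    duration_h: float = 72.0,
    plasma_callback: Callable[[float], float] | None = None,
    output_step_h: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    bottom_dirichlet: bool = True,
    store_fields: bool = True,
):
    """Solve a single-site transport problem with a prescribed plasma history.

    ``plasma_callback(t_s)`` supplies the plasma concentration (kg m^-3) at
    the dermis base; ``None`` means a perfect sink.  Returns
    ``(states, flux_series)`` where ``states`` is a list of
    :class:`TransportState` on the output grid (empty if ``store_fields`` is
    false) and ``flux_series`` a :class:`FluxSeries`.

    This entry point covers membrane-permeation analyses (lag-time checks,
    epidermis-only stacks); the fully coupled therapy simulation lives in
    :mod:`fentanyltwin.engine`.
    """
    from scipy import sparse
    from scipy.integrate import solve_ivp

    if grid is None:
        grid = Grid1D.build(stack)
    op = TransportOperator(grid, bottom_dirichlet=bottom_dirichlet)
    cb = plasma_callback or (lambda t: 0.0)
    n = grid.n_cells

    def rhs(t, psi):
        out = np.empty(n)
        op.rhs(psi, cb(t), out)
        return out

    psi0 = np.zeros(n)
    psi0[: grid.n_patch_cells] = stack.patch.initial_concentration_kg_m3 / stack.patch.layer.capacity
    jac = sparse.diags([np.ones(n - 1), np.ones(n), np.ones(n - 1)], [-1, 0, 1])
    t_out = np.arange(0.0, duration_h * HOUR_S + 1e-9, output_step_h * HOUR_S)
    sol = solve_ivp(
        rhs, (0.0, duration_h * HOUR_S), psi0, method="BDF", t_eval=t_out,
        rtol=rtol, atol=atol, jac_sparsity=jac,
    )
    if sol.status != 0:
        raise SolverFailureError(f"transport integration failed: {sol.message}")
    c0 = stack.patch.initial_concentration_kg_m3
    if c0 > 0 and sol.y.min() < -1e-6 * c0:
        raise SolverFailureError(
            f"negative drug potential beyond tolerance: min psi = {sol.y.min():.3e}"
        )
    flux_p = np.array([op.patch_outflux(sol.y[:, k]) for k in range(sol.t.size)])
    flux_d = np.array([op.blood_flux(sol.y[:, k], cb(tk)) for k, tk in enumerate(sol.t)])
    series = FluxSeries(
        time_h=sol.t / HOUR_S,
        flux_patch_ug_cm2_h=flux_p * FLUX_SI_TO_UG_CM2_H,
        flux_dermis_ug_cm2_h=flux_d * FLUX_SI_TO_UG_CM2_H,
    )
    states = (
        [TransportState(tk, sol.y[:, k].copy()) for k, tk in enumerate(sol.t)]
        if store_fields
        else []
    )
    return states, series
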