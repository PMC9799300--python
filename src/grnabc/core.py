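"""Negative-feedback gene-expression network: parameters, prior, truth grid.

The model is a single self-repressing gene (Hes1-like motif): the gene
transcribes mRNA in the nucleus, mRNA is translated to protein in the
cytoplasm, and protein diffuses back into the nucleus where it can bind the
gene and shut transcription off.  Five reactions describe the chemistry:

    G + P  <->  GP          (binding ka / unbinding kd, nucleus)
    G      ->   G + mRNA    (transcription mu, nucleus)
    mRNA   ->   mRNA + P    (translation kappa, cytoplasm)
    mRNA   ->   0           (degradation gamma, entire cell)
    P      ->   0           (degradation gamma, entire cell)

Two quantities are the inference targets: the diffusion coefficient D and a
dimensionless reactivity multiplier chi that scales transcription,
translation and degradation simultaneously (mu, kappa, gamma = chi * base).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

#: Base parameter values (chi = 1).  Lengths in um, D in um^2/min, ka in
#: M^-1 min^-1, all first-order rates in min^-1.
BASE_PARAMETERS = {
    "R": 6.0,
    "r": 2.5,
    "D": 0.6,
    "ka": 1.0e9,
    "kd": 0.1,
    "mu": 3.0,
    "kappa": 1.0,
    "gamma": 0.04,
}

MU_BASE = BASE_PARAMETERS["mu"]
KAPPA_BASE = BASE_PARAMETERS["kappa"]
GAMMA_BASE = BASE_PARAMETERS["gamma"]


@dataclass(frozen=True)
class ParameterSet:
    """Full biophysical parameter vector, with the chi multiplier recorded.

    chi is stored alongside the scaled rates rather than recomputed from
    them, so the (D, chi) inference coordinates round-trip exactly.
    """

    R: float
    r: float
    D: float
    ka: float
    kd: float
    mu: float
    kappa: float
    gamma: float
    chi: float

    def __post_init__(self) -> None:
        for name in ("R", "r", "D", "ka", "kd", "mu", "kappa", "gamma", "chi"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name} must be strictly positive, got {value}")
        if self.r >= self.R:
            raise ValueError(f"nucleus radius r={self.r} must be smaller than cell radius R={self.R}")

    @property
    def coordinates(self) -> tuple[float, float]:
        """The inferred coordinates (D, chi)."""
        return (self.D, self.chi)

    def to_json(self) -> str:
        payload = {
            "R_um": self.R,
            "r_um": self.r,
            "D_um2_per_min": self.D,
            "ka_per_molar_per_min": self.ka,
            "kd_per_min": self.kd,
            "mu_per_min": self.mu,
            "kappa_per_min": self.kappa,
            "gamma_per_min": self.gamma,
            "chi": self.chi,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        d = json.loads(text)
        return cls(
            R=d["R_um"],
            r=d["r_um"],
            D=d["D_um2_per_min"],
            ka=d["ka_per_molar_per_min"],
            kd=d["kd_per_min"],
            mu=d["mu_per_min"],
            kappa=d["kappa_per_min"],
            gamma=d["gamma_per_min"],
            chi=d["chi"],
        )


def make_parameters(chi: float, D: float) -> ParameterSet:
    """Build the parameter vector for a point (chi, D) of the inference space.

    mu, kappa and gamma are the base values scaled by chi; every other field
    keeps its base value.
    """
    if not np.isfinite(chi) or chi <= 0:
        raise ValueError(f"chi must be strictly positive, got {chi}")
    if not np.isfinite(D) or D <= 0:
        raise ValueError(f"D must be strictly positive, got {D}")
    return ParameterSet(
        R=BASE_PARAMETERS["R"],
        r=BASE_PARAMETERS["r"],
        D=float(D),
        ka=BASE_PARAMETERS["ka"],
        kd=BASE_PARAMETERS["kd"],
        mu=chi * MU_BASE,
        kappa=chi * KAPPA_BASE,
        gamma=chi * GAMMA_BASE,
        chi=float(chi),
    )


# ---------------------------------------------------------------------------
# Reaction network (declarative; simulators consume the matrices)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    name: str
    reactants: dict[str, int]
    products: dict[str, int]
    rate_constant: float
    localization: str  # "nucleus" | "cytoplasm" | "entire cell"


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]

    def stoichiometry_matrix(self) -> np.ndarray:
        """(n_reactions, n_species) net change per firing."""
        S = np.zeros((len(self.reactions), len(self.species)), dtype=np.int64)
        idx = {s: i for i, s in enumerate(self.species)}
        for j, rx in enumerate(self.reactions):
            for sp, n in rx.reactants.items():
                S[j, idx[sp]] -= n
            for sp, n in rx.products.items():
                S[j, idx[sp]] += n
        return S

    def order_matrix(self) -> np.ndarray:
        """(n_reactions, n_species) mass-action reactant orders."""
        O = np.zeros((len(self.reactions), len(self.species)), dtype=np.int64)
        idx = {s: i for i, s in enumerate(self.species)}
        for j, rx in enumerate(self.reactions):
            for sp, n in rx.reactants.items():
                O[j, idx[sp]] = n
        return O

    def rate_constants(self) -> np.ndarray:
        return np.array([rx.rate_constant for rx in self.reactions], dtype=np.float64)

    def propensities(self, state: Sequence[int]) -> np.ndarray:
        x = np.asarray(state, dtype=np.float64)
        O = self.order_matrix()
        c = self.rate_constants()
        return c * np.prod(np.where(O > 0, x[None, :] ** O, 1.0), axis=1)

    def gene_species(self) -> tuple[str, ...]:
        return tuple(s for s in self.species if s.startswith("G"))


def whole_cell_network(params: ParameterSet, binding_propensity: float) -> ReactionNetwork:
    """The five-reaction network with the whole cell as one mixed volume.

    binding_propensity is the per-pair association propensity (min^-1),
    i.e. the diffusion-limited effective rate divided by N_A * V_cell.
    """
    species = ("G_free", "G_bound", "mRNA", "P")
    reactions = (
        Reaction("binding", {"G_free": 1, "P": 1}, {"G_bound": 1}, binding_propensity, "nucleus"),
        Reaction("unbinding", {"G_bound": 1}, {"G_free": 1, "P": 1}, params.kd, "nucleus"),
        Reaction("transcription", {"G_free": 1}, {"G_free": 1, "mRNA": 1}, params.mu, "nucleus"),
        Reaction("translation", {"mRNA": 1}, {"mRNA": 1, "P": 1}, params.kappa, "cytoplasm"),
        Reaction("mrna_degradation", {"mRNA": 1}, {}, params.gamma, "entire cell"),
        Reaction("protein_degradation", {"P": 1}, {}, params.gamma, "entire cell"),
    )
    return ReactionNetwork(species, reactions)


def compartment_network(
    params: ParameterSet,
    binding_propensity_nuc: float,
    k_exit: float,
    k_entry: float,
) -> ReactionNetwork:
    """Two-compartment (nucleus/cytoplasm) version of the network.

    Transcription produces nuclear mRNA, translation happens only from
    cytoplasmic mRNA, gene binding only consumes nuclear protein, and both
    mobile species hop between compartments at first-passage-derived rates.
    """
    species = ("G_free", "G_bound", "mRNA_nuc", "mRNA_cyt", "P_nuc", "P_cyt")
    g = params.gamma
    reactions = (
        Reaction("binding", {"G_free": 1, "P_nuc": 1}, {"G_bound": 1}, binding_propensity_nuc, "nucleus"),
        Reaction("unbinding", {"G_bound": 1}, {"G_free": 1, "P_nuc": 1}, params.kd, "nucleus"),
        Reaction("transcription", {"G_free": 1}, {"G_free": 1, "mRNA_nuc": 1}, params.mu, "nucleus"),
        Reaction("translation", {"mRNA_cyt": 1}, {"mRNA_cyt": 1, "P_cyt": 1}, params.kappa, "cytoplasm"),
        Reaction("mrna_nuc_degradation", {"mRNA_nuc": 1}, {}, g, "entire cell"),
        Reaction("mrna_cyt_degradation", {"mRNA_cyt": 1}, {}, g, "entire cell"),
        Reaction("p_nuc_degradation", {"P_nuc": 1}, {}, g, "entire cell"),
        Reaction("p_cyt_degradation", {"P_cyt": 1}, {}, g, "entire cell"),
        Reaction("mrna_exit", {"mRNA_nuc": 1}, {"mRNA_cyt": 1}, k_exit, "entire cell"),
        Reaction("mrna_entry", {"mRNA_cyt": 1}, {"mRNA_nuc": 1}, k_entry, "entire cell"),
        Reaction("p_exit", {"P_nuc": 1}, {"P_cyt": 1}, k_exit, "entire cell"),
        Reaction("p_entry", {"P_cyt": 1}, {"P_nuc": 1}, k_entry, "entire cell"),
    )
    return ReactionNetwork(species, reactions)


# ---------------------------------------------------------------------------
# Prior and ground-truth grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Independent log-uniform prior over (D, chi)."""

    D_bounds: tuple[float, float] = (0.0039, 16.0)
    chi_bounds: tuple[float, float] = (0.25, 16.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.D_bounds, self.chi_bounds):
            if not (0 < lo < hi):
                raise ValueError("prior bounds must satisfy 0 < low < high")

    def contains(self, D: float, chi: float) -> bool:
        return (self.D_bounds[0] <= D <= self.D_bounds[1]) and (
            self.chi_bounds[0] <= chi <= self.chi_bounds[1]
        )

    def log_bounds(self) -> np.ndarray:
        """log10 bounds, rows = (D, chi), columns = (low, high)."""
        return np.log10(np.array([self.D_bounds, self.chi_bounds]))


def prior_sample(prior: PriorSpec, n: int, seed: int) -> np.ndarray:
    """n independent draws from the prior; columns (D, chi)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lb = prior.log_bounds()
    logs = rng.uniform(lb[:, 0], lb[:, 1], size=(n, 2))
    return 10.0**logs


@dataclass(frozen=True)
class ParameterGrid:
    """Geometric grid over (D, chi) spanning the prior bounds inclusively."""

    n_D: int
    n_chi: int
    D_values: tuple[float, ...]
    chi_values: tuple[float, ...]

    @property
    def points(self) -> list[tuple[float, float]]:
        """Row-major (D outer, chi inner) ordered list of (D, chi) pairs."""
        return [(D, chi) for D in self.D_values for chi in self.chi_values]

    def __len__(self) -> int:
        return self.n_D * self.n_chi

    def manifest_rows(self) -> list[dict]:
        return [
            {"index": i, "D": D, "chi": chi}
            for i, (D, chi) in enumerate(self.points)
        ]


def make_grid(n_D: int, n_chi: int, prior: PriorSpec | None = None) -> ParameterGrid:
    """Log-spaced grid including both prior endpoints on each axis."""
    if n_D < 2 or n_chi < 2:
        raise ValueError("grid needs at least 2 points per axis")
    prior = prior or PriorSpec()
    D_vals = np.logspace(np.log10(prior.D_bounds[0]), np.log10(prior.D_bounds[1]), n_D)
    chi_vals = np.logspace(np.log10(prior.chi_bounds[0]), np.log10(prior.chi_bounds[1]), n_chi)
    # force exact endpoints despite floating-point log/exp round trips
    D_vals[0], D_vals[-1] = prior.D_bounds
    chi_vals[0], chi_vals[-1] = prior.chi_bounds
    return ParameterGrid(n_D, n_chi, tuple(D_vals), tuple(chi_vals))
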