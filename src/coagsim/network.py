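"""Mass-action reaction networks for coagulation-cascade kinetics.

The package ships the Hockin-Mann model of the tissue-factor (extrinsic)
pathway as a YAML network file; :func:`load_network` parses and validates
it into a :class:`ReactionNetwork` that exposes vectorised mass-action
derivatives and an analytic Jacobian for stiff integration.

The network is closed (no synthesis or degradation), so the total amount
of each core protein, summed over its free and complexed forms, is an
invariant of the dynamics.  The ``moieties`` mapping in the network file
makes those conservation laws explicit, and validation checks every
reaction against them symbolically.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "NetworkError",
    "NetworkParseError",
    "NetworkValidationError",
    "load_network",
    "default_network_path",
]

#: name of the packaged Hockin-Mann network file
DEFAULT_NETWORK_RESOURCE = "hockin_mann_2002.yaml"


class NetworkError(Exception):
    """Base class for network file problems."""


class NetworkParseError(NetworkError):
    """The network file is malformed (names the offending record)."""


class NetworkValidationError(NetworkError):
    """The parsed network violates a structural invariant."""


@dataclass(frozen=True)
class Species:
    """One chemical species: a free protein or a complex.

    Parameters
    ----------
    name:
        Unique identifier, e.g. ``"Xa"`` or ``"TF=VIIa=Xa"``.
    initial_nM:
        Default initial concentration in nM (non-negative).
    randomized:
        Whether the species' initial level varies between individuals
        in a simulated population.
    """

    name: str
    initial_nM: float
    randomized: bool = False


@dataclass(frozen=True)
class Reaction:
    """An irreversible uni- or bimolecular mass-action step.

    Reversible steps are represented as two irreversible reactions.
    ``k`` is in 1/s for first-order and 1/(nM*s) for second-order steps.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k: float
    k_units: str = ""

    @property
    def order(self) -> int:
        return len(self.reactants)


class ReactionNetwork:
    """A validated closed mass-action network.

    Provides the ODE right-hand side and its Jacobian in nM/s, the
    default initial-concentration vector, and moiety bookkeeping.
    """

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        moieties: Mapping[str, Sequence[str]],
    ):
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        self.moieties = {p: tuple(members) for p, members in moieties.items()}
        self.index = {s.name: i for i, s in enumerate(self.species)}
        self._validate()
        self._build_arrays()

    # ------------------------------------------------------------------
    # construction / validation
    # ------------------------------------------------------------------
    def _validate(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise NetworkValidationError(f"duplicate species names: {dup}")
        for s in self.species:
            if s.initial_nM < 0:
                raise NetworkValidationError(
                    f"species {s.name!r}: negative initial concentration "
                    f"{s.initial_nM}"
                )
        for i, r in enumerate(self.reactions):
            label = f"reaction #{i + 1} ({'+'.join(r.reactants)} -> {'+'.join(r.products)})"
            for side in (r.reactants, r.products):
                for name in side:
                    if name not in self.index:
                        raise NetworkValidationError(
                            f"{label}: unknown species {name!r}"
                        )
            if not r.k > 0:
                raise NetworkValidationError(f"{label}: rate constant must be > 0, got {r.k}")
            if r.order not in (1, 2):
                raise NetworkValidationError(
                    f"{label}: reaction order {r.order} unsupported (only 1 or 2)"
                )
        for protein, members in self.moieties.items():
            for name in members:
                if name not in self.index:
                    raise NetworkValidationError(
                        f"moiety {protein!r}: unknown species {name!r}"
                    )
        # symbolic conservation check: for each moiety, every reaction must
        # leave the weighted species sum unchanged
        net = self._net_stoichiometry()
        for protein, members in self.moieties.items():
            w = np.zeros(len(self.species))
            w[[self.index[m] for m in members]] = 1.0
            change = w @ net  # per reaction
            bad = np.nonzero(change != 0.0)[0]
            if bad.size:
                i = int(bad[0])
                r = self.reactions[i]
                raise NetworkValidationError(
                    f"moiety {protein!r} not conserved by reaction #{i + 1} "
                    f"({'+'.join(r.reactants)} -> {'+'.join(r.products)}): "
                    f"net change {change[i]:+g}"
                )

    def _net_stoichiometry(self) -> np.ndarray:
        """Net stoichiometry matrix, species x reactions."""
        n_sp, n_rx = len(self.species), len(self.reactions)
        net = np.zeros((n_sp, n_rx))
        for j, r in enumerate(self.reactions):
            for name in r.reactants:
                net[self.index[name], j] -= 1.0
            for name in r.products:
                net[self.index[name], j] += 1.0
        return net

    def _build_arrays(self) -> None:
        n_sp = len(self.species)
        self._net = self._net_stoichiometry()
        self._k = np.array([r.k for r in self.reactions])
        # reactant index pairs; unimolecular steps point their second slot
        # at a padding entry that always holds 1.0
        pad = n_sp
        r1, r2 = [], []
        for r in self.reactions:
            r1.append(self.index[r.reactants[0]])
            r2.append(self.index[r.reactants[1]] if r.order == 2 else pad)
        self._r1 = np.array(r1)
        self._r2 = np.array(r2)
        self._pad = pad

    # ------------------------------------------------------------------
    # public API
    # ------------------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def initial_concentrations(self) -> np.ndarray:
        """Default initial concentration vector (nM), in species order."""
        return np.array([s.initial_nM for s in self.species])

    def randomized_species(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species if s.randomized)

    def reaction_rates(self, concentrations: np.ndarray) -> np.ndarray:
        """Mass-action rate of each reaction (nM/s) at the given state."""
        cp = np.empty(self.n_species + 1)
        cp[:-1] = concentrations
        cp[-1] = 1.0
        return self._k * cp[self._r1] * cp[self._r2]

    def mass_action_rhs(self, concentrations: np.ndarray) -> np.ndarray:
        """Time derivative of every species concentration, in nM/s.

        Each reaction contributes ``k * prod(reactant concentrations)``,
        removed from its reactants and added to its products.
        """
        c = np.asarray(concentrations, dtype=float)
        if c.shape != (self.n_species,):
            raise ValueError(
                f"expected concentration vector of length {self.n_species}, "
                f"got shape {c.shape}"
            )
        return self._net @ self.reaction_rates(c)

    def jacobian(self, concentrations: np.ndarray) -> np.ndarray:
        """Analytic Jacobian d(rhs)/d(concentrations), species x species."""
        cp = np.empty(self.n_species + 1)
        cp[:-1] = concentrations
        cp[-1] = 1.0
        n_rx = len(self.reactions)
        # d rate_j / d c_i, including the A+A case via accumulation
        d = np.zeros((n_rx, self.n_species + 1))
        rows = np.arange(n_rx)
        np.add.at(d, (rows, self._r1), self._k * cp[self._r2])
        np.add.at(d, (rows, self._r2), self._k * cp[self._r1])
        return self._net @ d[:, :-1]

    def moiety_totals(self, concentrations: np.ndarray) -> dict[str, float]:
        """Total of each conserved moiety at the given state (nM)."""
        c = np.asarray(concentrations, dtype=float)
        out = {}
        for protein, members in self.moieties.items():
            out[protein] = float(c[[self.index[m] for m in members]].sum())
        return out


# ----------------------------------------------------------------------
# file I/O
# ----------------------------------------------------------------------

def default_network_path() -> Path:
    """Path of the packaged Hockin-Mann network file."""
    return Path(str(resources.files("coagsim.data") / DEFAULT_NETWORK_RESOURCE))


def load_network(network_file: str | Path | None = None) -> ReactionNetwork:
    """Load and validate a reaction network from a YAML file.

    With no argument, loads the packaged Hockin-Mann tissue-factor
    pathway model (34 species, 43 irreversible mass-action steps).

    Raises
    ------
    NetworkParseError
        If the file cannot be read or a record is malformed.
    NetworkValidationError
        If the parsed network violates an invariant (unknown species,
        non-positive rate constant, broken moiety conservation, ...).
    """
    path = Path(network_file) if network_file is not None else default_network_path()
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise NetworkParseError(f"network file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise NetworkParseError(f"invalid YAML in {path}: {exc}") from exc

    if not isinstance(raw, dict):
        raise NetworkParseError(f"{path}: top level must be a mapping")
    for key in ("species", "reactions"):
        if key not in raw:
            raise NetworkParseError(f"{path}: missing required section {key!r}")

    species = []
    for i, rec in enumerate(raw["species"]):
        try:
            species.append(
                Species(
                    name=str(rec["name"]),
                    initial_nM=float(rec["initial_nM"]),
                    randomized=bool(rec.get("randomized", False)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise NetworkParseError(f"{path}: species record #{i + 1}: {exc}") from exc

    reactions = []
    for i, rec in enumerate(raw["reactions"]):
        try:
            reactions.append(
                Reaction(
                    reactants=tuple(str(n) for n in rec["reactants"]),
                    products=tuple(str(n) for n in rec["products"]),
                    k=float(rec["k"]),
                    k_units=str(rec.get("k_units", "")),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise NetworkParseError(f"{path}: reaction record #{i + 1}: {exc}") from exc

    moieties = raw.get("moieties", {})
    return ReactionNetwork(species, reactions, moieties)
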