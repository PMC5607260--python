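"""Declarative description of the receptor signaling network.

The network couples five receptor tyrosine kinases (EGFR, HER2, ErbB3, Met,
IGF-1R) through ligand binding, spontaneous and ligand-driven dimerization,
trafficking of active dimers, and a two-branch downstream cascade
(MEK->ERK and AKT, converging on S6K1 and S6).  The only cell-line-specific
quantity anywhere in the model is the receptor surface expression carried by
:class:`CellLineContext`; all kinetic rates are shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

RECEPTORS: tuple[str, ...] = ("EGFR", "HER2", "ErbB3", "Met", "IGF1R")

#: ligand -> (receptor, dissociation constant K_D in nM).  The K_D values are
#: literature-scale defaults (nanomolar affinities of the growth factors for
#: their receptors); they are free parameters of the model configuration.
LIGANDS: dict[str, tuple[str, float]] = {
    "EGF": ("EGFR", 2.0),
    "HRG": ("ErbB3", 0.8),
    "HGF": ("Met", 0.4),
    "IGF1": ("IGF1R", 1.0),
    "BTC": ("EGFR", 1.5),
}

#: the ten dimers of the default network: five homodimers plus the five
#: heterodimers with biological evidence that survived model reduction.
FULL_DIMERS: tuple[tuple[str, str], ...] = (
    ("EGFR", "EGFR"),
    ("HER2", "HER2"),
    ("ErbB3", "ErbB3"),
    ("Met", "Met"),
    ("IGF1R", "IGF1R"),
    ("EGFR", "HER2"),
    ("EGFR", "ErbB3"),
    ("EGFR", "Met"),
    ("HER2", "ErbB3"),
    ("ErbB3", "Met"),
)

#: the two IGF-1R heterodimers that can be removed without loss of fit.
IGF1R_HETERODIMERS: tuple[tuple[str, str], ...] = (
    ("EGFR", "IGF1R"),
    ("HER2", "IGF1R"),
)

#: the experimental sampling grid in minutes (untreated zero plus stimulated
#: time points up to four hours).
DEFAULT_TIME_GRID: tuple[float, ...] = (0, 2, 4, 6, 8, 10, 15, 30, 60, 90, 120, 240)

#: ligand doses of the proliferation screen, nM.
SCREEN_DOSES: dict[str, float] = {"EGF": 5.0, "HRG": 5.0, "HGF": 1.0, "IGF1": 50.0}

VARIANTS = ("full", "no_igf1r_heterodimers", "no_heterodimers",
            "with_igf1r_heterodimers", "custom")


class StructureError(ValueError):
    """A network definition violates its structural invariants."""


def canonical_pair(a: str, b: str, receptors: tuple[str, ...] = RECEPTORS) -> tuple[str, str]:
    """Order a receptor pair by the canonical receptor order."""
    if a not in receptors or b not in receptors:
        raise StructureError(f"dimer ({a}, {b}) references a receptor outside {receptors}")
    return (a, b) if receptors.index(a) <= receptors.index(b) else (b, a)


def dimer_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}-{pair[1]}"


@dataclass(frozen=True)
class ModelSpec:
    """Structure of the signaling network.

    Parameters
    ----------
    receptors
        Ordered receptor identifiers.
    ligands
        Mapping ligand name -> (receptor, K_D in nM).
    dimers
        Ordered list of canonical receptor pairs.
    signaling_mask
        Per-dimer flag: can the dimer trans-phosphorylate and signal
        downstream?  The ErbB3 homodimer is kinase-dead in the default
        network and only regains signaling in the ``no_heterodimers``
        variant, where every receptor must signal through its homodimer.
    variant
        Name of the structural variant this spec encodes.
    feedback_links
        ``(source phospho-species, target pathway input, sign)`` triples;
        the default wiring is pERK inhibiting the MAPK input and pS6K1
        inhibiting the PI3K input.
    """

    receptors: tuple[str, ...] = RECEPTORS
    ligands: dict[str, tuple[str, float]] = field(default_factory=lambda: dict(LIGANDS))
    dimers: tuple[tuple[str, str], ...] = FULL_DIMERS
    signaling_mask: dict[tuple[str, str], bool] = field(default_factory=dict)
    variant: str = "full"
    feedback_links: tuple[tuple[str, str, int], ...] = (
        ("pERK", "MAPK", -1),
        ("pS6K1", "PI3K", -1),
    )

    def __post_init__(self):
        mask = dict(self.signaling_mask)
        for pair in self.dimers:
            if pair not in mask:
                # ErbB3 cannot trans-phosphorylate; its homodimer is silent
                # unless the variant removes all heterodimers.
                if pair == ("ErbB3", "ErbB3") and self.variant != "no_heterodimers":
                    mask[pair] = False
                else:
                    mask[pair] = True
        object.__setattr__(self, "signaling_mask", mask)
        object.__setattr__(self, "ligands", dict(self.ligands))
        object.__setattr__(self, "dimers", tuple(tuple(p) for p in self.dimers))
        self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def full(cls) -> "ModelSpec":
        return cls(variant="full")

    @classmethod
    def no_heterodimers(cls) -> "ModelSpec":
        homodimers = tuple((r, r) for r in RECEPTORS)
        return cls(dimers=homodimers, variant="no_heterodimers")

    @classmethod
    def with_igf1r_heterodimers(cls) -> "ModelSpec":
        return cls(dimers=FULL_DIMERS + IGF1R_HETERODIMERS, variant="with_igf1r_heterodimers")

    @classmethod
    def from_variant(cls, variant: str) -> "ModelSpec":
        if variant in ("full", "no_igf1r_heterodimers"):
            # the default ten-dimer network already omits the IGF-1R
            # heterodimers, so both names resolve to the same structure
            return replace(cls.full(), variant=variant) if variant != "full" else cls.full()
        if variant == "no_heterodimers":
            return cls.no_heterodimers()
        if variant == "with_igf1r_heterodimers":
            return cls.with_igf1r_heterodimers()
        raise StructureError(f"unknown variant {variant!r}; expected one of {VARIANTS}")

    @classmethod
    def custom(
        cls,
        receptors: tuple[str, ...],
        ligands: dict[str, tuple[str, float]] | None = None,
        heterodimers: tuple[tuple[str, str], ...] = (),
        variant: str = "custom",
        signaling_mask: dict | None = None,
    ) -> "ModelSpec":
        """Scaled-down network over a receptor subset (homodimers implied)."""
        ligands = ligands if ligands is not None else {
            lig: rk for lig, rk in LIGANDS.items() if rk[0] in receptors
        }
        dimers = tuple((r, r) for r in receptors) + tuple(
            canonical_pair(a, b, receptors) for a, b in heterodimers
        )
        return cls(
            receptors=receptors,
            ligands=ligands,
            dimers=dimers,
            variant=variant,
            signaling_mask=signaling_mask or {},
        )

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "receptors": list(self.receptors),
            "ligands": {lig: [rec, kd] for lig, (rec, kd) in self.ligands.items()},
            "dimers": [list(p) for p in self.dimers],
            "signaling_mask": {dimer_name(p): bool(v)
                               for p, v in self.signaling_mask.items()},
            "variant": self.variant,
            "feedback_links": [list(fb) for fb in self.feedback_links],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        dimers = tuple(tuple(p) for p in data["dimers"])
        mask = {tuple(name.split("-")): v
                for name, v in data.get("signaling_mask", {}).items()}
        return cls(
            receptors=tuple(data["receptors"]),
            ligands={lig: (rec, float(kd)) for lig, (rec, kd) in data["ligands"].items()},
            dimers=dimers,
            signaling_mask=mask,
            variant=data.get("variant", "custom"),
            feedback_links=tuple(tuple(fb) for fb in data.get("feedback_links", ())),
        )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        seen = set()
        for pair in self.dimers:
            if canonical_pair(pair[0], pair[1], self.receptors) != pair:
                raise StructureError(f"dimer {pair} is not in canonical order")
            if pair in seen:
                raise StructureError(f"duplicate dimer {pair}")
            seen.add(pair)
        for lig, (rec, kd) in self.ligands.items():
            if rec not in self.receptors:
                raise StructureError(f"ligand {lig} targets unknown receptor {rec}")
            if kd <= 0:
                raise StructureError(f"ligand {lig} has non-positive K_D")
        if self.variant == "full":
            if set(self.dimers) != set(FULL_DIMERS):
                raise StructureError("full variant must contain exactly the ten canonical dimers")
            if self.signaling_mask[("ErbB3", "ErbB3")]:
                raise StructureError("ErbB3 homodimer must be non-signaling in the full variant")
        if self.variant == "no_heterodimers":
            if any(a != b for a, b in self.dimers):
                raise StructureError("no_heterodimers variant must contain homodimers only")
            if not all(self.signaling_mask[p] for p in self.dimers):
                raise StructureError("all homodimers signal in the no_heterodimers variant")

    @property
    def signaling_dimers(self) -> tuple[tuple[str, str], ...]:
        return tuple(p for p in self.dimers if self.signaling_mask[p])

    def ligands_of(self, receptor: str) -> tuple[str, ...]:
        return tuple(lig for lig, (rec, _) in self.ligands.items() if rec == receptor)


@dataclass(frozen=True)
class CellLineContext:
    """Receptor surface expression and mutation flags for one cell line.

    ``receptor_expression`` is in molecules/cell.  The mutation flags are data
    for the downstream classifier only; they never alter the ODE structure.
    """

    name: str
    receptor_expression: dict[str, float]
    kras_mutant: bool = False
    pik3ca_mutant: bool = False
    igf1r_imputed: bool = False

    def __post_init__(self):
        for rec, val in self.receptor_expression.items():
            if val < 0:
                raise ValueError(f"{self.name}: negative expression for {rec}")

    def vector(self, spec: ModelSpec):
        import numpy as np

        return np.array([self.receptor_expression.get(r, 0.0) for r in spec.receptors])

    def scaled(self, factor: float) -> "CellLineContext":
        return replace(
            self,
            receptor_expression={r: v * factor for r, v in self.receptor_expression.items()},
        )


@dataclass(frozen=True)
class StimulusCondition:
    """Ligand doses (nM, held constant: bath application) and a time grid."""

    doses: dict[str, float] = field(default_factory=dict)
    horizon: float = 240.0
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID

    def __post_init__(self):
        grid = tuple(float(t) for t in self.time_grid)
        if grid[0] != 0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("time grid must be strictly increasing and start at 0")
        if grid[-1] > self.horizon:
            raise ValueError("time grid exceeds horizon")
        if any(d < 0 for d in self.doses.values()):
            raise ValueError("doses must be non-negative")
        object.__setattr__(self, "time_grid", grid)
        object.__setattr__(self, "doses", dict(self.doses))

    @property
    def is_basal(self) -> bool:
        return all(d == 0 for d in self.doses.values())

    def label(self) -> str:
        """Canonical condition string, e.g. ``"EGF:5+HRG:2.5"`` or ``"basal"``."""
        parts = [f"{lig}:{dose:g}" for lig, dose in sorted(self.doses.items()) if dose > 0]
        return "+".join(parts) if parts else "basal"

    @classmethod
    def from_label(cls, label: str, horizon: float = 240.0,
                   time_grid: tuple[float, ...] = DEFAULT_TIME_GRID) -> "StimulusCondition":
        doses: dict[str, float] = {}
        if label not in ("", "basal"):
            for part in label.split("+"):
                lig, _, dose = part.partition(":")
                doses[lig] = float(dose)
        return cls(doses=doses, horizon=horizon, time_grid=time_grid)
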