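"""Shared kinetic parameters of the signaling model.

One :class:`KineticParameterSet` is shared across all cell lines; only the
receptor expression in :class:`~ligandtree.network.CellLineContext` differs
between lines.  Units: time in min, receptor/dimer abundances in
molecules/cell, ligand doses in nM (binding rates absorb the volume
conversion), downstream species as active fractions of a conserved total.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import yaml

from .network import ModelSpec, canonical_pair, dimer_name


class ConfigurationError(ValueError):
    """A kinetic parameter is missing or outside its admissible range."""


# Pathway weights encode which dimers drive which cascade: ErbB3- and
# IGF-1R-containing dimers couple strongly to PI3K (ErbB3 carries the p85
# docking sites), EGFR/HER2/Met dimers drive MAPK, and IGF-1R activates MAPK
# only weakly.  The kinase-dead ErbB3 homodimer gets zero weight.
_DEFAULT_WEIGHTS: dict[str, tuple[float, float]] = {  # name -> (w_mapk, w_pi3k)
    "EGFR-EGFR": (1.0, 0.3),
    "HER2-HER2": (0.5, 0.2),
    "ErbB3-ErbB3": (0.0, 0.0),
    "Met-Met": (1.0, 0.6),
    "IGF1R-IGF1R": (0.2, 1.0),
    "EGFR-HER2": (1.0, 0.3),
    "EGFR-ErbB3": (0.5, 1.0),
    "EGFR-Met": (0.8, 0.5),
    "HER2-ErbB3": (0.5, 1.0),
    "ErbB3-Met": (0.5, 1.0),
    "EGFR-IGF1R": (0.2, 0.5),
    "HER2-IGF1R": (0.2, 0.5),
}

_DEFAULT_DIMER_RATES = {
    "ka": 2e-8,   # association, per (molecules/cell) per min
    "kd": 0.1,    # dissociation of the surface dimer, 1/min
    "kint": 0.05, # internalization of the (phospho-)dimer, 1/min
    "krec": 0.03, # recycling of the internalized dimer to free monomers, 1/min
    "kdeg": 0.01, # lysosomal degradation of the internalized dimer, 1/min
}

# Trafficking differs between dimers: EGFR homodimers are internalized fast
# but recycle efficiently, whereas HER2-containing heterodimers are routed to
# degradation.  These differences are what let one shared parameter set
# produce sustained receptor phosphorylation in EGFR-high lines (homodimer
# dominated) and transient phosphorylation in EGFR-low lines (heterodimer
# dominated).
_DIMER_RATE_OVERRIDES: dict[str, dict[str, float]] = {
    "EGFR-EGFR": {"kint": 0.10, "krec": 0.09, "kdeg": 0.005},
    "EGFR-HER2": {"kint": 0.15, "krec": 0.01, "kdeg": 0.05},
    "HER2-ErbB3": {"kint": 0.08, "krec": 0.01, "kdeg": 0.03},
}

_DEFAULT_DOWNSTREAM = {
    "kact_mek": 5.0,
    "kdeact_mek": 1.0,
    "kact_erk": 5.0,
    "kdeact_erk": 1.0,
    "kact_akt": 5.0,
    "kdeact_akt": 1.0,
    "kact_s6k1_erk": 2.0,
    "kact_s6k1_akt": 2.0,
    "kdeact_s6k1": 1.0,
    "kact_s6": 2.0,
    "kdeact_s6": 1.0,
    # negative-feedback strengths (pERK on the MAPK input, SOS-like;
    # pS6K1 on the PI3K input, IRS-1-like), dimensionless
    "fb_erk": 5.0,
    "fb_s6k1": 5.0,
    # reference abundance converting summed dimer signal to a
    # dimensionless cascade drive
    "signal_scale": 1e5,
}

# Ligand-specific dimerization preferences relative to the spontaneous rate.
# EGF-bound EGFR preferentially recruits HER2 over the other partners,
# while BTC drives EGFR homodimerization harder than the EGFR-HER2 pairing.
_DEFAULT_LIGAND_DIMER_MULTIPLIERS: dict[str, dict[str, float]] = {
    "EGF": {"EGFR-HER2": 2.0, "EGFR-ErbB3": 0.05, "EGFR-Met": 0.05, "EGFR-IGF1R": 0.05},
    "BTC": {"EGFR-EGFR": 3.0, "EGFR-HER2": 0.3},
}

_POSITIVE_DIMER_KEYS = ("ka", "kd", "kint", "krec", "kdeg")


@dataclass
class KineticParameterSet:
    """All kinetic rates, pathway weights and global options of the model.

    Fields mirror the reaction inventory: per-receptor synthesis/turnover,
    per-ligand binding, per-dimer association/trafficking, downstream
    cascade rates, feedback strengths, and per-ligand dimerization
    multipliers.  Every rate must be positive; pathway weights, feedback
    strengths and multipliers must be non-negative.
    """

    receptor: dict[str, dict[str, float]] = field(default_factory=dict)
    ligand: dict[str, dict[str, float]] = field(default_factory=dict)
    dimer: dict[str, dict[str, float]] = field(default_factory=dict)
    downstream: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_DOWNSTREAM))
    ligand_dimer_multiplier: dict[str, dict[str, float]] = field(default_factory=dict)
    #: enhancement of dimerization competence of a ligand-bound monomer
    phi_ligand: float = 250.0
    #: do internalized dimers keep signaling downstream?
    internal_signaling: bool = True

    # -- construction -----------------------------------------------------
    @classmethod
    def defaults(cls, spec: ModelSpec) -> "KineticParameterSet":
        receptor = {
            r: {"synth": 1.0, "kdeg": 0.005} for r in spec.receptors
        }
        ligand = {lig: {"kon": 0.1} for lig in spec.ligands}
        dimer = {}
        for pair in spec.dimers:
            name = dimer_name(pair)
            entry = dict(_DEFAULT_DIMER_RATES)
            entry.update(_DIMER_RATE_OVERRIDES.get(name, {}))
            w_mapk, w_pi3k = _DEFAULT_WEIGHTS.get(name, (0.5, 0.5))
            if not spec.signaling_mask[pair]:
                w_mapk = w_pi3k = 0.0
            elif name == "ErbB3-ErbB3":
                # only the no-heterodimer variant lets the ErbB3 homodimer
                # signal (PI3K-dominated, like the other ErbB3 dimers)
                w_mapk, w_pi3k = 0.5, 1.0
            entry["w_mapk"], entry["w_pi3k"] = w_mapk, w_pi3k
            dimer[name] = entry
        mult = {
            lig: dict(table)
            for lig, table in _DEFAULT_LIGAND_DIMER_MULTIPLIERS.items()
            if lig in spec.ligands
        }
        return cls(receptor=receptor, ligand=ligand, dimer=dimer,
                   ligand_dimer_multiplier=mult)

    # -- validation --------------------------------------------------------
    def validate(self, spec: ModelSpec) -> None:
        for r in spec.receptors:
            if r not in self.receptor:
                raise ConfigurationError(f"missing receptor parameters for {r!r}")
            for key in ("synth", "kdeg"):
                if key not in self.receptor[r]:
                    raise ConfigurationError(f"missing receptor/{r}/{key}")
                if self.receptor[r][key] <= 0:
                    raise ConfigurationError(f"receptor/{r}/{key} must be > 0")
        for lig in spec.ligands:
            if lig not in self.ligand or "kon" not in self.ligand[lig]:
                raise ConfigurationError(f"missing ligand parameters for {lig!r} (key 'kon')")
            if self.ligand[lig]["kon"] <= 0:
                raise ConfigurationError(f"ligand/{lig}/kon must be > 0")
        for pair in spec.dimers:
            name = dimer_name(pair)
            if name not in self.dimer:
                raise ConfigurationError(f"missing dimer parameters for {name!r}")
            entry = self.dimer[name]
            for key in _POSITIVE_DIMER_KEYS:
                if key not in entry:
                    raise ConfigurationError(f"missing dimer/{name}/{key}")
                if entry[key] <= 0:
                    raise ConfigurationError(f"dimer/{name}/{key} must be > 0")
            for key in ("w_mapk", "w_pi3k"):
                if key not in entry:
                    raise ConfigurationError(f"missing dimer/{name}/{key}")
                if entry[key] < 0:
                    raise ConfigurationError(f"dimer/{name}/{key} must be >= 0")
                if not spec.signaling_mask[pair] and entry[key] != 0:
                    raise ConfigurationError(
                        f"dimer/{name}/{key} must be 0 for a non-signaling dimer"
                    )
        for key, default in _DEFAULT_DOWNSTREAM.items():
            if key not in self.downstream:
                raise ConfigurationError(f"missing downstream/{key}")
        for key, value in self.downstream.items():
            floor = 0.0 if key.startswith("fb_") else None
            if floor is not None:
                if value < floor:
                    raise ConfigurationError(f"downstream/{key} must be >= 0")
            elif value <= 0:
                raise ConfigurationError(f"downstream/{key} must be > 0")
        if self.phi_ligand <= 0:
            raise ConfigurationError("phi_ligand must be > 0")
        for lig, table in self.ligand_dimer_multiplier.items():
            for name, m in table.items():
                if m < 0:
                    raise ConfigurationError(f"multiplier {lig}/{name} must be >= 0")

    # -- parameter paths (used by the calibration module) ------------------
    def get_path(self, path: str) -> float:
        parts = path.split("/")
        node = getattr(self, parts[0])
        for p in parts[1:-1]:
            node = node[p]
        return node[parts[-1]] if isinstance(node, dict) else getattr(node, parts[-1])

    def set_path(self, path: str, value: float) -> None:
        parts = path.split("/")
        try:
            node = getattr(self, parts[0])
        except AttributeError as exc:
            raise ConfigurationError(f"unknown parameter group {parts[0]!r}") from exc
        for p in parts[1:-1]:
            if p not in node:
                raise ConfigurationError(f"unknown parameter path {path!r}")
            node = node[p]
        if parts[-1] not in node:
            raise ConfigurationError(f"unknown parameter path {path!r}")
        node[parts[-1]] = value

    def copy(self) -> "KineticParameterSet":
        return copy.deepcopy(self)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "receptor": copy.deepcopy(self.receptor),
            "ligand": copy.deepcopy(self.ligand),
            "dimer": copy.deepcopy(self.dimer),
            "downstream": dict(self.downstream),
            "ligand_dimer_multiplier": copy.deepcopy(self.ligand_dimer_multiplier),
            "phi_ligand": self.phi_ligand,
            "internal_signaling": self.internal_signaling,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "KineticParameterSet":
        return cls(**copy.deepcopy(data))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "KineticParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- convenience -------------------------------------------------------
    def multiplier(self, ligand: str, name: str) -> float:
        return self.ligand_dimer_multiplier.get(ligand, {}).get(name, 1.0)

    def koff(self, spec: ModelSpec, ligand: str) -> float:
        _, kd = spec.ligands[ligand]
        return kd * self.ligand[ligand]["kon"]
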