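"""Monoisotopic mass arithmetic for crosslinked peptides.

Everything downstream of the mass spectrometer reduces to sums of a small
number of exact constants: residue masses, water, protons, the mass added by
an amine-reactive crosslinker, and the per-nitrogen shift of metabolic 15N
labelling.  This module owns those sums.  Neutral monoisotopic masses are the
canonical internal representation; m/z appears only at the I/O boundary
(:func:`mass_to_mz` / :func:`mz_to_mass`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "ResidueMassTable",
    "CrosslinkerDef",
    "ModKind",
    "Modification",
    "PeptideSpec",
    "CrosslinkedPair",
    "BS3",
    "BS2G",
    "DEFAULT_MASS_TABLE",
    "N15_SHIFT_PER_N",
    "peptide_nitrogens",
    "peptide_mass",
    "pair_mass",
    "mass_to_mz",
    "mz_to_mass",
    "ppm_error",
    "reactive_amine_count",
    "load_crosslinkers",
]

#: Mass difference between a 15N and a 14N atom (Da).
N15_SHIFT_PER_N = 0.997035

_WATER = 18.0105646863
_PROTON = 1.00727646688

# Standard monoisotopic residue (amino-acid minus water) masses, Da.
_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

# Nitrogen atoms per residue (backbone amide N included).
_RESIDUE_N = {
    "G": 1, "A": 1, "S": 1, "P": 1, "V": 1, "T": 1, "C": 1, "L": 1,
    "I": 1, "N": 2, "D": 1, "Q": 2, "K": 2, "E": 1, "M": 1, "H": 3,
    "F": 1, "R": 4, "Y": 1, "W": 2,
}


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses and per-residue nitrogen counts."""

    residue_mass: Mapping[str, float] = field(default_factory=lambda: dict(_RESIDUE_MASS))
    nitrogen_count: Mapping[str, int] = field(default_factory=lambda: dict(_RESIDUE_N))
    water: float = _WATER
    proton: float = _PROTON

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.residue_mass)
        if missing:
            raise ValueError(f"mass table missing residues: {sorted(missing)}")
        if any(m <= 0 for m in self.residue_mass.values()):
            raise ValueError("residue masses must be positive")
        if any(self.nitrogen_count.get(r, 0) < 1 for r in self.residue_mass):
            raise ValueError("every residue contains at least one nitrogen")
        for r in "KR":
            if self.nitrogen_count[r] <= 1:
                raise ValueError(f"{r} side chain carries extra nitrogen")


DEFAULT_MASS_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class CrosslinkerDef:
    """An amine-reactive homobifunctional crosslinker.

    ``bridge_mass`` is the mass added when both ester ends have reacted with
    amines; ``deadend_hydrolyzed_mass`` when one end reacted and the other
    hydrolyzed (it retains one water equivalent); ``deadend_tris_mass`` when
    the free end was quenched by Tris (optional, off by default).  ``span`` is
    the nominal maximum Calpha-Calpha distance the crosslinker can bridge, in
    angstrom.
    """

    name: str
    bridge_mass: float
    deadend_hydrolyzed_mass: float
    span: float
    deadend_tris_mass: Optional[float] = None

    def __post_init__(self) -> None:
        if self.span <= 0:
            raise ValueError("span must be positive")
        if not self.bridge_mass < self.deadend_hydrolyzed_mass:
            raise ValueError("deadend retains one water equivalent; must exceed bridge mass")


# Bridge masses from the diacid elemental formulas (suberate C8H10O2,
# glutarate C5H4O2 after double amide formation); deadend = bridge + H2O.
BS3 = CrosslinkerDef("BS3", 138.06808, 156.07864, span=30.0)
BS2G = CrosslinkerDef("BS2G", 96.02113, 114.03169, span=30.0)

_BUILTIN_LINKERS = {"BS3": BS3, "BS2G": BS2G}


def get_crosslinker(name: str) -> CrosslinkerDef:
    try:
        return _BUILTIN_LINKERS[name.upper().replace("-", "")]
    except KeyError:
        raise KeyError(f"unknown crosslinker {name!r}; built-ins: BS3, BS2G") from None


def load_crosslinkers(text: str) -> dict[str, CrosslinkerDef]:
    """Parse crosslinker definitions from plain-text config.

    One definition per line::

        name  bridge_mass  deadend_hydrolyzed_mass  span  [deadend_tris_mass]

    Lines starting with ``#`` are comments.
    """
    out: dict[str, CrosslinkerDef] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (4, 5):
            raise ValueError(f"bad crosslinker line: {line!r}")
        name = parts[0]
        bridge, deadend, span = (float(x) for x in parts[1:4])
        tris = float(parts[4]) if len(parts) == 5 else None
        out[name] = CrosslinkerDef(name, bridge, deadend, span, tris)
    return out


class ModKind(Enum):
    DEADEND_HYDROLYZED = "hydrolyzed-deadend"
    DEADEND_TRIS = "tris-deadend"
    LOOPLINK = "internal-looplink"


@dataclass(frozen=True)
class Modification:
    """A crosslinker-derived modification on one peptide.

    ``site`` is the 1-based position within the peptide sequence.  For a
    looplink the second bridged amine is implied (any other reactive amine in
    the peptide).
    """

    kind: ModKind
    site: int
    linker: CrosslinkerDef

    @property
    def mass(self) -> float:
        if self.kind is ModKind.DEADEND_HYDROLYZED:
            return self.linker.deadend_hydrolyzed_mass
        if self.kind is ModKind.DEADEND_TRIS:
            if self.linker.deadend_tris_mass is None:
                raise ValueError(
                    f"{self.linker.name} has no Tris-quenched deadend mass configured"
                )
            return self.linker.deadend_tris_mass
        return self.linker.bridge_mass  # looplink: both ends in the same peptide


MAX_MODS_PER_PEPTIDE = 3


@dataclass(frozen=True)
class PeptideSpec:
    """A proteolytic peptide with provenance, modifications and isotope label."""

    sequence: str
    protein_id: str = "protein"
    start: int = 1
    end: int = 0  # 0 -> inferred from start + len(sequence) - 1
    modifications: tuple[Modification, ...] = ()
    label: str = "14N"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        bad = [c for c in self.sequence if c not in _RESIDUE_MASS]
        if bad:
            raise ValueError(f"unknown residue letter(s) {bad!r} in {self.sequence!r}")
        if self.end == 0:
            object.__setattr__(self, "end", self.start + len(self.sequence) - 1)
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"positions {self.start}-{self.end} inconsistent with "
                f"sequence length {len(self.sequence)}"
            )
        if self.label not in ("14N", "15N"):
            raise ValueError(f"label must be '14N' or '15N', got {self.label!r}")
        if len(self.modifications) > MAX_MODS_PER_PEPTIDE:
            raise ValueError(f"more than {MAX_MODS_PER_PEPTIDE} modifications per peptide")
        for m in self.modifications:
            if not 1 <= m.site <= len(self.sequence):
                raise ValueError(f"modification site {m.site} outside peptide")
            if m.kind is ModKind.LOOPLINK and self.sequence.count("K") + (
                1 if self.start == 1 else 0
            ) < 2:
                raise ValueError("internal looplink needs >= 2 reactive amines")

    def with_label(self, label: str) -> "PeptideSpec":
        return PeptideSpec(
            self.sequence, self.protein_id, self.start, self.end,
            self.modifications, label,
        )


@dataclass(frozen=True)
class CrosslinkedPair:
    """Two peptides bridged by a crosslinker at specific protein positions."""

    peptide_a: PeptideSpec
    peptide_b: PeptideSpec
    link_pos_a: int  # 1-based position in protein A
    link_pos_b: int
    linker: CrosslinkerDef = BS3

    def __post_init__(self) -> None:
        for pep, pos in ((self.peptide_a, self.link_pos_a), (self.peptide_b, self.link_pos_b)):
            if not pep.start <= pos <= pep.end:
                raise ValueError(f"link position {pos} outside peptide span {pep.start}-{pep.end}")
            local = pos - pep.start
            if pep.sequence[local] != "K" and pos != 1:
                raise ValueError(
                    f"link position {pos} ({pep.sequence[local]}) is neither a lysine "
                    "nor the protein N-terminus"
                )

    @property
    def isotope_state(self) -> str:
        return f"{self.peptide_a.label[:2]}/{self.peptide_b.label[:2]}"


def peptide_nitrogens(p: PeptideSpec | str, t: ResidueMassTable = DEFAULT_MASS_TABLE) -> int:
    """Total nitrogen atoms over the peptide's residues."""
    seq = p if isinstance(p, str) else p.sequence
    if not seq:
        raise ValueError("empty peptide sequence")
    try:
        return sum(t.nitrogen_count[c] for c in seq)
    except KeyError as e:
        raise ValueError(f"unknown residue letter {e.args[0]!r}") from None


def peptide_mass(p: PeptideSpec, t: ResidueMassTable = DEFAULT_MASS_TABLE) -> float:
    """Neutral monoisotopic peptide mass, modifications and isotope label included.

    The 15N shift applies to protein-derived nitrogens only; crosslinker atoms
    come from the unlabeled reagent.
    """
    try:
        m = sum(t.residue_mass[c] for c in p.sequence) + t.water
    except KeyError as e:
        raise ValueError(f"unknown residue letter {e.args[0]!r}") from None
    m += sum(mod.mass for mod in p.modifications)
    if p.label == "15N":
        m += N15_SHIFT_PER_N * peptide_nitrogens(p, t)
    return m


def pair_mass(x: CrosslinkedPair, t: ResidueMassTable = DEFAULT_MASS_TABLE) -> float:
    """Neutral mass of a crosslinked peptide pair: mass(A) + mass(B) + bridge.

    Labels apply per peptide independently, so hybrid 14N/15N pairs come out
    shifted by the partner's nitrogen count alone.
    """
    return peptide_mass(x.peptide_a, t) + peptide_mass(x.peptide_b, t) + x.linker.bridge_mass


def mass_to_mz(mass: float, charge: int, proton: float = _PROTON) -> float:
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * proton) / charge


def mz_to_mass(mz: float, charge: int, proton: float = _PROTON) -> float:
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * proton


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def reactive_amine_count(sequence: str, protein_nterm: bool = True) -> int:
    """Crosslinker-reactive primary amines in a protein/peptide sequence.

    Counts lysine side-chain amines plus (optionally) the protein N-terminal
    alpha-amine.
    """
    if not sequence:
        raise ValueError("empty sequence")
    return sequence.count("K") + (1 if protein_nterm else 0)
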