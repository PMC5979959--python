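"""Mapping crosslinks onto structural models.

A lysine-specific crosslinker with ~11 A spacer can bridge Calpha atoms up to
roughly 30 A apart once side-chain and backbone flexibility are accounted
for; a crosslink whose modeled Calpha-Calpha distance exceeds 40 A is
implausible ("violating") and counts as evidence against the model.  This
module evaluates crosslink-derived distance constraints on candidate models,
ranks the candidates (zero-violation models first, then by number of
satisfied constraints), classifies crosslinks by domain topology and
intra-/inter-subunit possibility, and exports the constraints as docking
restraints.

Distances are Calpha-Calpha throughout.  On homo-oligomeric models a
constraint is evaluated as the minimum over all chain assignments; a
same-to-same-residue crosslink (e.g. K189xK189) can only be realized between
distinct chains and is unevaluable on a monomer.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "StructureModel",
    "CrosslinkConstraint",
    "ConstraintPolicy",
    "DomainMap",
    "ConstraintEvaluation",
    "ModelReport",
    "load_structure",
    "load_structure_file",
    "ca_distance",
    "evaluate_constraint",
    "evaluate_model",
    "rank_models",
    "rank_models_from_distances",
    "classify_topology",
    "export_restraints_tsv",
    "export_restraints_air",
    "read_constraints_tsv",
    "structure_to_pdb",
]

SATISFIED = "satisfied"
AMBIGUOUS = "ambiguous"
VIOLATED = "violated"


@dataclass
class StructureModel:
    """Calpha-only structural model keyed by (chain id, author residue number).

    ``chains`` maps chain id to an ordered mapping residue number ->
    (residue name, Calpha coordinate).  Author numbering from the PDB is kept
    as-is and assumed to match 1-based sequence positions.
    """

    model_id: str
    chains: dict[str, dict[int, tuple[str, np.ndarray]]]

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def ca(self, chain: str, resnum: int) -> np.ndarray:
        try:
            return self.chains[chain][resnum][1]
        except KeyError:
            raise KeyError(f"no Calpha for chain {chain!r} residue {resnum}") from None

    def residue_numbers(self, chain: Optional[str] = None) -> list[int]:
        if chain is None:
            chain = self.chain_ids[0]
        return list(self.chains[chain])

    def coords(self, chain: Optional[str] = None) -> np.ndarray:
        """(N, 3) Calpha coordinate array for one chain (default: first)."""
        if chain is None:
            chain = self.chain_ids[0]
        return np.array([xyz for _, xyz in self.chains[chain].values()], dtype=float)

    def all_coords(self) -> np.ndarray:
        """(N, 3) coordinates over all chains, chain order preserved."""
        return np.vstack([self.coords(c) for c in self.chain_ids])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigidly moved copy (x -> R x + t)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        chains = {
            cid: {num: (name, R @ xyz + t) for num, (name, xyz) in residues.items()}
            for cid, residues in self.chains.items()
        }
        return StructureModel(self.model_id, chains)

    def with_coords(self, coords: np.ndarray, chain: Optional[str] = None) -> "StructureModel":
        """Copy with one chain's Calpha coordinates replaced (same residue order)."""
        if chain is None:
            chain = self.chain_ids[0]
        residues = self.chains[chain]
        if len(coords) != len(residues):
            raise ValueError("coordinate count does not match residue count")
        new = {cid: dict(res) for cid, res in self.chains.items()}
        new[chain] = {
            num: (name, np.asarray(xyz, dtype=float))
            for (num, (name, _)), xyz in zip(residues.items(), coords)
        }
        return StructureModel(self.model_id, new)


def _from_gemmi(st: gemmi.Structure, model_id: str) -> StructureModel:
    chains: dict[str, dict[int, tuple[str, np.ndarray]]] = {}
    if len(st) == 0:
        raise ValueError("structure contains no models")
    model = st[0]
    for chain in model:
        residues: dict[int, tuple[str, np.ndarray]] = {}
        for res in chain:
            ca = res.find_atom("CA", "*")
            if ca is None:
                warnings.warn(
                    f"residue {chain.name}/{res.seqid.num} {res.name} has no CA; skipped"
                )
                continue
            num = res.seqid.num
            if num in residues:
                raise ValueError(f"duplicate residue number {num} in chain {chain.name}")
            residues[num] = (res.name, np.array([ca.pos.x, ca.pos.y, ca.pos.z]))
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise ValueError("no Calpha atoms found")
    return StructureModel(model_id, chains)


def load_structure(pdb_text: str, model_id: str = "model") -> StructureModel:
    """Parse standard PDB text into a Calpha-only :class:`StructureModel`."""
    if not pdb_text.strip():
        raise ValueError("empty PDB input")
    st = gemmi.read_pdb_string(pdb_text)
    return _from_gemmi(st, model_id)


def load_structure_file(path: str, model_id: Optional[str] = None) -> StructureModel:
    st = gemmi.read_structure(str(path))
    return _from_gemmi(st, model_id or st.name or str(path))


def structure_to_pdb(models: "StructureModel | Sequence[StructureModel]") -> str:
    """Write one model (or a multi-model trajectory) as PDB text, Calpha only."""
    if isinstance(models, StructureModel):
        models = [models]
    lines: list[str] = []
    multi = len(models) > 1
    for i, m in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        serial = 1
        for cid, residues in m.chains.items():
            for num, (name, xyz) in residues.items():
                lines.append(
                    f"ATOM  {serial:5d}  CA  {name:>3s} {cid[:1]}{num:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
                )
                serial += 1
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class CrosslinkConstraint:
    """A crosslink between two residue positions of the same protein."""

    pos_a: int
    pos_b: int
    linker: str = "BS3"
    evidence: tuple[str, ...] = ()

    @property
    def same_residue(self) -> bool:
        return self.pos_a == self.pos_b

    @property
    def label(self) -> str:
        return f"K{self.pos_a}xK{self.pos_b}"


@dataclass(frozen=True)
class ConstraintPolicy:
    """Distance thresholds for classifying crosslink constraints.

    ``satisfied_max``: maximum Calpha-Calpha distance a crosslink can
    plausibly bridge (inclusive).  ``violation_min``: distance beyond which a
    crosslink is implausible (exclusive lower edge of the violated class).
    Distances in between are ambiguous.
    """

    satisfied_max: float = 30.0
    violation_min: float = 40.0

    def __post_init__(self) -> None:
        if not 0 < self.satisfied_max < self.violation_min:
            raise ValueError("need 0 < satisfied_max < violation_min")

    def classify(self, distance: float) -> str:
        if distance <= self.satisfied_max:
            return SATISFIED
        if distance > self.violation_min:
            return VIOLATED
        return AMBIGUOUS


@dataclass(frozen=True)
class DomainMap:
    """Named, non-overlapping residue ranges (1-based, inclusive)."""

    ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"NTD": (1, 71), "middle": (72, 189), "CTD": (190, 241)}
    )

    def __post_init__(self) -> None:
        spans = sorted(self.ranges.values())
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError("domain ranges overlap")
        if any(a < 1 or b < a for a, b in spans):
            raise ValueError("bad domain range")

    def domain_of(self, pos: int) -> Optional[str]:
        for name, (a, b) in self.ranges.items():
            if a <= pos <= b:
                return name
        return None


def ca_distance(m: StructureModel, a: int, b: int, chain_a: Optional[str] = None,
                chain_b: Optional[str] = None) -> float:
    """Euclidean Calpha-Calpha distance between two residues (angstrom)."""
    ca_chain = chain_a or m.chain_ids[0]
    cb_chain = chain_b or m.chain_ids[0]
    return float(np.linalg.norm(m.ca(ca_chain, a) - m.ca(cb_chain, b)))


@dataclass(frozen=True)
class ConstraintEvaluation:
    constraint: CrosslinkConstraint
    distance: Optional[float]  # None when unevaluable
    klass: str  # satisfied / ambiguous / violated / unevaluable
    realization: str  # "intra-chain", "inter-chain A-B", or "inter-only, unevaluable"


def evaluate_constraint(m: StructureModel, c: CrosslinkConstraint,
                        policy: ConstraintPolicy = ConstraintPolicy()) -> ConstraintEvaluation:
    """Evaluate one constraint on a model.

    For multi-chain homo-oligomers the reported distance is the minimum over
    all chain assignments.  Same-residue constraints are evaluated only across
    distinct chains; on a single-chain model they are marked unevaluable.
    """
    best: Optional[tuple[float, str]] = None
    cids = m.chain_ids
    for ca_id in cids:
        if c.pos_a not in m.chains[ca_id]:
            continue
        for cb_id in cids:
            if c.pos_b not in m.chains[cb_id]:
                continue
            if c.same_residue and ca_id == cb_id:
                continue
            d = ca_distance(m, c.pos_a, c.pos_b, ca_id, cb_id)
            tag = "intra-chain" if ca_id == cb_id else f"inter-chain {ca_id}-{cb_id}"
            if best is None or d < best[0]:
                best = (d, tag)
    if best is None:
        if c.same_residue and len(cids) == 1:
            return ConstraintEvaluation(c, None, "unevaluable", "inter-only, unevaluable")
        raise KeyError(
            f"constraint {c.label}: residue {c.pos_a} or {c.pos_b} missing from model "
            f"{m.model_id!r}"
        )
    d, tag = best
    return ConstraintEvaluation(c, d, policy.classify(d), tag)


@dataclass
class ModelReport:
    """Per-model constraint evaluation summary."""

    model_id: str
    evaluations: list[ConstraintEvaluation]

    @property
    def n_satisfied(self) -> int:
        return sum(e.klass == SATISFIED for e in self.evaluations)

    @property
    def n_ambiguous(self) -> int:
        return sum(e.klass == AMBIGUOUS for e in self.evaluations)

    @property
    def n_violated(self) -> int:
        return sum(e.klass == VIOLATED for e in self.evaluations)

    @property
    def mean_distance(self) -> float:
        ds = [e.distance for e in self.evaluations if e.distance is not None]
        return float(np.mean(ds)) if ds else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "constraint": [e.constraint.label for e in self.evaluations],
                "distance_a": [e.distance for e in self.evaluations],
                "class": [e.klass for e in self.evaluations],
                "realization": [e.realization for e in self.evaluations],
            }
        )


def evaluate_model(m: StructureModel, constraints: Sequence[CrosslinkConstraint],
                   policy: ConstraintPolicy = ConstraintPolicy()) -> ModelReport:
    return ModelReport(m.model_id, [evaluate_constraint(m, c, policy) for c in constraints])


def _rank_key(report: ModelReport):
    # zero-violation tier first, then more satisfied, fewer violations,
    # lower mean distance, then id for determinism
    return (
        0 if report.n_violated == 0 else 1,
        -report.n_satisfied,
        report.n_violated,
        report.mean_distance if np.isfinite(report.mean_distance) else float("inf"),
        report.model_id,
    )


def rank_models(models: Sequence[StructureModel],
                constraints: Sequence[CrosslinkConstraint],
                policy: ConstraintPolicy = ConstraintPolicy(),
                ) -> tuple[ModelReport, list[ModelReport]]:
    """Rank candidate models against crosslink constraints.

    Returns ``(selected, ranking)`` where ``ranking`` is best-first.  Models
    without violating crosslinks rank above any model with violations; within
    a tier, more satisfied constraints win; ties break by lower mean distance,
    then model id.
    """
    if not models:
        raise ValueError("no models to rank")
    if not constraints:
        warnings.warn("no constraints given; all models tie")
    reports = [evaluate_model(m, constraints, policy) for m in models]
    reports.sort(key=_rank_key)
    return reports[0], reports


def rank_models_from_distances(distances: pd.DataFrame,
                               policy: ConstraintPolicy = ConstraintPolicy(),
                               ) -> tuple[ModelReport, list[ModelReport]]:
    """Rank models from a precomputed constraint x model distance table.

    ``distances``: rows are constraints, columns are model ids, values are
    Calpha-Calpha distances in angstrom.  The index (or a 'constraint' column
    of labels like ``K196xK29``) names the constraints.  This is the entry
    point for published distance matrices where the underlying coordinates
    are not at hand.
    """
    df = distances.copy()
    if "constraint" in df.columns:
        df = df.set_index("constraint")
    reports = []
    for model_id in df.columns:
        evals = []
        for label, d in df[model_id].items():
            pos = _parse_label(str(label))
            c = CrosslinkConstraint(*pos)
            d = float(d)
            evals.append(ConstraintEvaluation(c, d, policy.classify(d), "intra-chain"))
        reports.append(ModelReport(str(model_id), evals))
    reports.sort(key=_rank_key)
    return reports[0], reports


def _parse_label(label: str) -> tuple[int, int]:
    parts = label.upper().replace("K", "").split("X")
    if len(parts) != 2:
        raise ValueError(f"cannot parse constraint label {label!r} (expected e.g. K196xK29)")
    return int(parts[0]), int(parts[1])


def classify_topology(c: CrosslinkConstraint, domains: DomainMap = DomainMap(),
                      model: Optional[StructureModel] = None) -> tuple[str, str]:
    """Classify a crosslink by domain topology and subunit possibility.

    Returns ``(domain_class, subunit_class)`` where ``domain_class`` is
    ``"intra-domain (X)"`` or ``"inter-domain (X-Y)"`` (or
    ``"linker/unassigned"``) and ``subunit_class`` is ``"inter-only"`` for
    same-to-same-residue crosslinks (realizable only between subunits) else
    ``"intra-possible"``.
    """
    da = domains.domain_of(c.pos_a)
    db = domains.domain_of(c.pos_b)
    if da is None or db is None:
        domain_class = "linker/unassigned"
    elif da == db:
        domain_class = f"intra-domain ({da})"
    else:
        domain_class = f"inter-domain ({da}-{db})"
    subunit_class = "inter-only" if c.same_residue else "intra-possible"
    return domain_class, subunit_class


def export_restraints_tsv(constraints: Sequence[CrosslinkConstraint],
                          policy: ConstraintPolicy = ConstraintPolicy()) -> str:
    """Restraints as TSV: residue pairs with the satisfied-distance upper bound."""
    if not constraints:
        raise ValueError("no constraints to export")
    buf = io.StringIO()
    buf.write("pos_a\tpos_b\tlinker\tupper_bound_a\n")
    for c in constraints:
        buf.write(f"{c.pos_a}\t{c.pos_b}\t{c.linker}\t{policy.satisfied_max:g}\n")
    return buf.getvalue()


def export_restraints_air(constraints: Sequence[CrosslinkConstraint],
                          policy: ConstraintPolicy = ConstraintPolicy(),
                          segid_a: str = "A", segid_b: str = "B") -> str:
    """Ambiguous distance restraints for information-driven docking.

    One CNS-style ``assign`` statement per constraint between Calpha atoms of
    the two subunits, allowed range 0 .. upper bound (encoded as
    ``d dminus dplus`` = ``u u 0``).
    """
    if not constraints:
        raise ValueError("no constraints to export")
    u = policy.satisfied_max
    lines = []
    for c in constraints:
        lines.append(
            f"assign (segid {segid_a} and resid {c.pos_a} and name CA) "
            f"(segid {segid_b} and resid {c.pos_b} and name CA) "
            f"{u:.1f} {u:.1f} 0.0"
        )
    return "\n".join(lines) + "\n"


def read_constraints_tsv(text: str) -> list[CrosslinkConstraint]:
    """Parse the TSV written by :func:`export_restraints_tsv` (round-trip)."""
    df = pd.read_csv(io.StringIO(text), sep="\t")
    return [
        CrosslinkConstraint(int(r.pos_a), int(r.pos_b), str(r.linker))
        for r in df.itertuples()
    ]
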