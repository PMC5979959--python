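"""In-silico digestion and crosslink identification from MGF peak lists.

A minimal, transparent re-implementation of the search stage of a
crosslinking-MS experiment: proteins are digested in silico (trypsin plus
low-specificity chymotrypsin, missed cleavages allowed), every crosslinkable
peptide pair / deadend / internal looplink is enumerated with its neutral
monoisotopic mass, spectra are matched first on precursor mass (ppm
tolerance, charge 2+ excluded since crosslinked peptides are usually 3+ or
higher) and then on b/y fragment ions (Da tolerance), and candidate matches
are scored and flagged against the acceptance criteria used in manual
validation (signal present from both peptides, few major peaks unexplained).

With metabolic 14N/15N labelling enabled, every candidate is considered in
all four isotope states; hybrid (14/15 or 15/14) crosslinks between subunits
mixed *before* crosslinking - and their absence in a crosslinked-then-mixed
control - demonstrate oligomer subunit exchange.
"""

from __future__ import annotations

import io
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .chem import (
    BS3,
    DEFAULT_MASS_TABLE,
    CrosslinkedPair,
    CrosslinkerDef,
    ModKind,
    Modification,
    PeptideSpec,
    N15_SHIFT_PER_N,
    mass_to_mz,
    mz_to_mass,
    pair_mass,
    peptide_mass,
    peptide_nitrogens,
    ppm_error,
)

__all__ = [
    "SearchSettings",
    "SpectrumRecord",
    "Candidate",
    "CandidateMatch",
    "HybridVerdict",
    "ENZYME_SITES",
    "digest",
    "reactive_positions",
    "enumerate_candidates",
    "filter_top_peaks",
    "precursor_match",
    "theoretical_fragments",
    "score_match",
    "search_spectra",
    "best_matches",
    "detect_hybrids",
    "read_mgf",
    "write_mgf",
    "read_fasta",
    "matches_to_frame",
]

# Cleavage specificity, C-terminal to the listed residues, blocked by a
# following proline.  Chymotrypsin is the low-specificity variant (F/W/Y/L/M).
ENZYME_SITES: Mapping[str, frozenset] = {
    "trypsin": frozenset("KR"),
    "chymotrypsin": frozenset("FWYLM"),
}


@dataclass(frozen=True)
class SearchSettings:
    """Search tolerances, digestion rules and acceptance thresholds."""

    ms1_ppm: float = 10.0
    ms2_da: float = 0.05
    enzymes: tuple[str, ...] = ("trypsin", "chymotrypsin")
    max_missed_cleavages: int = 2
    max_mods_per_peptide: int = 3
    top_n_peaks: int = 125
    min_precursor_charge: int = 3
    min_matched_intensity: float = 1000.0
    require_both_peptides: bool = True
    max_unexplained_fraction: float = 0.3
    min_peptide_length: int = 2

    def __post_init__(self) -> None:
        if self.ms1_ppm <= 0 or self.ms2_da <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_missed_cleavages < 0:
            raise ValueError("missed cleavages must be >= 0")
        if self.top_n_peaks < 1:
            raise ValueError("top-N peak filter must keep at least one peak")
        for e in self.enzymes:
            if e not in ENZYME_SITES:
                raise ValueError(f"unknown enzyme {e!r}")


@dataclass
class SpectrumRecord:
    """One MS/MS spectrum: precursor and centroided peak list."""

    title: str
    precursor_mz: float
    charge: Optional[int]
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("peak arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]


def digest(sequence: str, settings: SearchSettings = SearchSettings(),
           protein_id: str = "protein") -> list[PeptideSpec]:
    """All peptides from cleavage after the enzyme-specific residues.

    Cleavage is C-terminal to K/R (trypsin) and F/W/Y/L/M (chymotrypsin),
    never before proline, with 0..max missed cleavages.  Positions are
    1-based within the protein.  An empty enzyme set returns the whole
    protein.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    sites: set[str] = set()
    for e in settings.enzymes:
        sites |= set(ENZYME_SITES[e])
    bounds = [0]
    for i, c in enumerate(sequence[:-1]):
        if c in sites and sequence[i + 1] != "P":
            bounds.append(i + 1)
    bounds.append(len(sequence))
    peptides = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + settings.max_missed_cleavages, len(bounds))):
            seq = sequence[bounds[a]:bounds[b]]
            if len(seq) < settings.min_peptide_length:
                continue
            peptides.append(PeptideSpec(seq, protein_id, start=bounds[a] + 1))
    return peptides


def reactive_positions(pep: PeptideSpec, protein_length: Optional[int] = None,
                       nterm_reactive: bool = True) -> list[int]:
    """Protein positions in this peptide with a crosslinker-reactive amine.

    Lysine side chains count unless the lysine sits at the peptide
    C-terminus as a cleavage product (a crosslinker-carrying lysine is not
    cleaved by trypsin, so such a lysine must be unmodified).  The protein
    N-terminal alpha-amine is reactive; peptide N-termini created by
    digestion are not, because crosslinking precedes digestion.
    """
    out = []
    if nterm_reactive and pep.start == 1:
        out.append(1)
    n = len(pep.sequence)
    for i, c in enumerate(pep.sequence):
        pos = pep.start + i
        if c != "K":
            continue
        if i == n - 1 and (protein_length is None or pep.end != protein_length):
            continue  # C-terminal cleavage-product lysine
        if pos not in out:
            out.append(pos)
    return out


@dataclass(frozen=True)
class Candidate:
    """A searchable species: crosslinked pair, deadend or internal looplink."""

    kind: str  # "crosslink" | "deadend" | "looplink"
    pair: Optional[CrosslinkedPair]
    peptide: Optional[PeptideSpec]
    candidate_id: str
    neutral_mass: float  # all-14N mass
    n_nitrogens: tuple[int, int]  # (peptide A, peptide B); B = 0 for singles

    def isotope_states(self, labeling: bool) -> dict[str, float]:
        """Mass shift per isotope state (Da)."""
        na, nb = self.n_nitrogens
        if self.kind == "crosslink":
            if not labeling:
                return {"14/14": 0.0}
            return {
                "14/14": 0.0,
                "14/15": N15_SHIFT_PER_N * nb,
                "15/14": N15_SHIFT_PER_N * na,
                "15/15": N15_SHIFT_PER_N * (na + nb),
            }
        if not labeling:
            return {"14": 0.0}
        return {"14": 0.0, "15": N15_SHIFT_PER_N * na}


def _pair_id(a: PeptideSpec, pa: int, b: PeptideSpec, pb: int, linker: str) -> str:
    left = f"{a.protein_id}:{a.sequence}@{pa}"
    right = f"{b.protein_id}:{b.sequence}@{pb}"
    if right < left:
        left, right = right, left
    return f"XL[{linker}]{left}--{right}"


def enumerate_candidates(peptides: Sequence[PeptideSpec],
                         linker: CrosslinkerDef = BS3,
                         settings: SearchSettings = SearchSettings(),
                         protein_lengths: Optional[Mapping[str, int]] = None,
                         ) -> list[Candidate]:
    """Enumerate crosslink / deadend / looplink candidates over a digest.

    Pairs require one reactive amine per peptide (a peptide may pair with a
    second copy of itself: same-to-same links are legal and, in
    homo-oligomers, diagnostic of inter-subunit contacts).  All reactive-site
    combinations are enumerated; modification counts respect the per-peptide
    maximum.
    """
    plen = protein_lengths or {}
    candidates: list[Candidate] = []
    seen: set[str] = set()
    reactive = [
        (p, reactive_positions(p, plen.get(p.protein_id))) for p in peptides
    ]
    for p, rp in reactive:
        if not rp or len(p.modifications) + 1 > settings.max_mods_per_peptide:
            continue
        local = rp[0] - p.start + 1
        dead = PeptideSpec(
            p.sequence, p.protein_id, p.start, p.end,
            p.modifications + (Modification(ModKind.DEADEND_HYDROLYZED, local, linker),),
        )
        cid = f"DE[{linker.name}]{p.protein_id}:{p.sequence}@{rp[0]}"
        if cid not in seen:
            seen.add(cid)
            candidates.append(Candidate(
                "deadend", None, dead, cid, peptide_mass(dead),
                (peptide_nitrogens(dead), 0),
            ))
        if len(rp) >= 2:
            loop = PeptideSpec(
                p.sequence, p.protein_id, p.start, p.end,
                p.modifications + (Modification(ModKind.LOOPLINK, local, linker),),
            )
            cid = f"LL[{linker.name}]{p.protein_id}:{p.sequence}@{rp[0]}-{rp[1]}"
            if cid not in seen:
                seen.add(cid)
                candidates.append(Candidate(
                    "looplink", None, loop, cid, peptide_mass(loop),
                    (peptide_nitrogens(loop), 0),
                ))
    indexed = [(p, rp) for p, rp in reactive if rp]
    for i, (pa, rpa) in enumerate(indexed):
        for pb, rpb in indexed[i:]:
            if (len(pa.modifications) + 1 > settings.max_mods_per_peptide
                    or len(pb.modifications) + 1 > settings.max_mods_per_peptide):
                continue
            for pos_a, pos_b in itertools.product(rpa, rpb):
                cid = _pair_id(pa, pos_a, pb, pos_b, linker.name)
                if cid in seen:
                    continue
                seen.add(cid)
                pair = CrosslinkedPair(pa, pb, pos_a, pos_b, linker)
                candidates.append(Candidate(
                    "crosslink", pair, None, cid, pair_mass(pair),
                    (peptide_nitrogens(pa), peptide_nitrogens(pb)),
                ))
    return candidates


def filter_top_peaks(spec: SpectrumRecord, n: int) -> SpectrumRecord:
    """Keep the n most intense peaks, m/z order preserved; idempotent."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(spec.mz) <= n:
        return spec
    order = np.lexsort((spec.mz, -spec.intensity))[:n]
    keep = np.sort(order)
    return SpectrumRecord(spec.title, spec.precursor_mz, spec.charge,
                          spec.mz[keep], spec.intensity[keep])


@dataclass
class CandidateMatch:
    """A candidate explaining one spectrum, with score and validation flags."""

    spectrum_id: str
    candidate: Candidate
    isotope_state: str
    ppm: float
    score: float = 0.0
    per_peptide_matches: tuple[int, int] = (0, 0)
    both_peptides: bool = False
    unexplained_fraction: float = 1.0
    matched_intensity: float = 0.0
    accepted: bool = False


def precursor_match(spec: SpectrumRecord, candidates: Sequence[Candidate],
                    settings: SearchSettings = SearchSettings(),
                    labeling: bool = False) -> list[CandidateMatch]:
    """Candidates whose neutral mass matches the spectrum precursor.

    All isotope states are considered when labelling is enabled.  Spectra
    without a charge are skipped with a warning; spectra below the minimum
    precursor charge (default 3+, i.e. excluding 2+) are skipped silently.
    """
    if spec.charge is None:
        warnings.warn(f"spectrum {spec.title!r} has no charge; skipped")
        return []
    if spec.charge < settings.min_precursor_charge:
        return []
    neutral = mz_to_mass(spec.precursor_mz, spec.charge)
    out = []
    for cand in candidates:
        for state, shift in cand.isotope_states(labeling).items():
            err = ppm_error(neutral, cand.neutral_mass + shift)
            if abs(err) <= settings.ms1_ppm:
                out.append(CandidateMatch(spec.title, cand, state, err))
    return out


def _residue_masses(pep: PeptideSpec, label_15n: bool) -> np.ndarray:
    t = DEFAULT_MASS_TABLE
    m = np.array([t.residue_mass[c] for c in pep.sequence])
    if label_15n:
        m += N15_SHIFT_PER_N * np.array([t.nitrogen_count[c] for c in pep.sequence])
    for mod in pep.modifications:
        m[mod.site - 1] += mod.mass
    return m


@dataclass(frozen=True)
class Fragment:
    mz: float
    ion: str            # e.g. "A.b3+1"
    peptide_index: int  # 0 or 1


def theoretical_fragments(candidate: "Candidate | CrosslinkedPair",
                          max_fragment_charge: int = 2,
                          isotope_state: Optional[str] = None) -> list[Fragment]:
    """b/y fragment ions of a candidate.

    For crosslinked pairs, fragments that span the linked residue carry the
    full partner peptide plus the bridge as a fixed added mass (the
    crosslink does not fragment under CID).  Looplink fragments between the
    two bridged sites are treated as carrying the intact bridge - a
    deliberate simplification of ring-opening chemistry.  Charges run from 1
    to ``max_fragment_charge``.
    """
    t = DEFAULT_MASS_TABLE
    if isinstance(candidate, CrosslinkedPair):
        pair = candidate
        kind = "crosslink"
        single = None
    else:
        pair = candidate.pair
        kind = candidate.kind
        single = candidate.peptide

    def labels(default_a: bool, default_b: bool) -> tuple[bool, bool]:
        if isotope_state is None:
            return default_a, default_b
        parts = isotope_state.split("/")
        a15 = parts[0] == "15"
        b15 = parts[-1] == "15" if len(parts) > 1 else False
        return a15, b15

    frags: list[Fragment] = []

    def add_series(pep: PeptideSpec, masses: np.ndarray, link_local: Optional[int],
                   partner_add: float, tag: str, pidx: int) -> None:
        n = len(masses)
        prefix = np.cumsum(masses)
        total = prefix[-1]
        for i in range(1, n):
            b = prefix[i - 1]
            y = total - prefix[i - 1] + t.water
            if link_local is not None:
                if link_local <= i:          # b_i spans the link site
                    b += partner_add
                if link_local > i:           # y_(n-i) spans the link site
                    y += partner_add
            for z in range(1, max_fragment_charge + 1):
                frags.append(Fragment((b + z * t.proton) / z, f"{tag}.b{i}+{z}", pidx))
                frags.append(Fragment((y + z * t.proton) / z, f"{tag}.y{n - i}+{z}", pidx))

    if kind == "crosslink":
        assert pair is not None
        a15, b15 = labels(pair.peptide_a.label == "15N", pair.peptide_b.label == "15N")
        pa = pair.peptide_a.with_label("15N" if a15 else "14N")
        pb = pair.peptide_b.with_label("15N" if b15 else "14N")
        ma = _residue_masses(pa, a15)
        mb = _residue_masses(pb, b15)
        add_a = peptide_mass(pb) + pair.linker.bridge_mass
        add_b = peptide_mass(pa) + pair.linker.bridge_mass
        add_series(pa, ma, pair.link_pos_a - pa.start + 1, add_a, "A", 0)
        add_series(pb, mb, pair.link_pos_b - pb.start + 1, add_b, "B", 1)
    else:
        assert single is not None
        a15, _ = labels(single.label == "15N", False)
        m = _residue_masses(single.with_label("15N" if a15 else "14N"), a15)
        add_series(single, m, None, 0.0, "A", 0)
    return frags


@dataclass
class MatchScore:
    score: float
    per_peptide_matches: tuple[int, int]
    both_peptides: bool
    unexplained_fraction: float
    matched_intensity: float


def score_match(spec: SpectrumRecord, fragments: Sequence[Fragment],
                settings: SearchSettings = SearchSettings()) -> MatchScore:
    """Fragment-level evidence for a candidate.

    The score is the matched fraction of theoretical fragments multiplied by
    the matched fraction of total peak intensity (both shrink monotonically
    as the MS2 tolerance tightens).  Flags capture the manual-validation
    criteria: fragments observed from both peptides, and the fraction of the
    top-20 most intense peaks left unexplained.
    """
    if len(spec.mz) == 0 or not fragments:
        return MatchScore(0.0, (0, 0), False, 1.0, 0.0)
    mz = spec.mz
    matched_peaks = np.zeros(len(mz), dtype=bool)
    counts = [0, 0]
    n_matched_frags = 0
    for f in fragments:
        i = np.searchsorted(mz, f.mz)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(mz):
                d = abs(mz[j] - f.mz)
                if d <= settings.ms2_da and (best is None or d < best[0]):
                    best = (d, j)
        if best is not None:
            matched_peaks[best[1]] = True
            counts[f.peptide_index] += 1
            n_matched_frags += 1
    total_int = float(spec.intensity.sum())
    matched_int = float(spec.intensity[matched_peaks].sum())
    frag_fraction = n_matched_frags / len(fragments)
    int_fraction = matched_int / total_int if total_int > 0 else 0.0
    score = frag_fraction * int_fraction
    is_pair = any(f.peptide_index == 1 for f in fragments)
    both = counts[0] > 0 and (counts[1] > 0 or not is_pair)
    top20 = np.argsort(-spec.intensity, kind="stable")[:20]
    unexplained = float(np.mean(~matched_peaks[top20])) if len(top20) else 1.0
    return MatchScore(score, (counts[0], counts[1]), both, unexplained, matched_int)


def search_spectra(spectra: Sequence[SpectrumRecord],
                   candidates: Sequence[Candidate],
                   settings: SearchSettings = SearchSettings(),
                   labeling: bool = False,
                   max_fragment_charge: int = 2) -> list[CandidateMatch]:
    """Full search: top-N peak filter, precursor match, fragment scoring.

    Returns all tolerance-passing matches; per spectrum they are ordered by
    descending score, then smaller |ppm|, then candidate id (deterministic
    tie-break).
    """
    results: list[CandidateMatch] = []
    for spec in spectra:
        spec_f = filter_top_peaks(spec, settings.top_n_peaks)
        prelim = precursor_match(spec_f, candidates, settings, labeling)
        for m in prelim:
            frags = theoretical_fragments(m.candidate, max_fragment_charge,
                                          isotope_state=m.isotope_state)
            s = score_match(spec_f, frags, settings)
            m.score = s.score
            m.per_peptide_matches = s.per_peptide_matches
            m.both_peptides = s.both_peptides
            m.unexplained_fraction = s.unexplained_fraction
            m.matched_intensity = s.matched_intensity
            m.accepted = (
                s.matched_intensity >= settings.min_matched_intensity
                and (s.both_peptides or not settings.require_both_peptides)
                and s.unexplained_fraction <= settings.max_unexplained_fraction
            )
        prelim.sort(key=lambda m: (-m.score, abs(m.ppm), m.candidate.candidate_id))
        results.extend(prelim)
    return results


def best_matches(matches: Sequence[CandidateMatch]) -> dict[str, CandidateMatch]:
    """Top-ranked match per spectrum (input must be search_spectra output order)."""
    out: dict[str, CandidateMatch] = {}
    for m in matches:
        if m.spectrum_id not in out:
            out[m.spectrum_id] = m
    return out


@dataclass
class HybridVerdict:
    exchange: bool
    hybrids_mixed: list[CandidateMatch]
    hybrids_control: list[CandidateMatch]


def _hybrids(matches: Iterable[CandidateMatch]) -> list[CandidateMatch]:
    return [m for m in matches if m.isotope_state in ("14/15", "15/14")]


def detect_hybrids(mixed_matches: Sequence[CandidateMatch],
                   control_matches: Sequence[CandidateMatch],
                   labeling_enabled: bool = True,
                   accepted_only: bool = True) -> HybridVerdict:
    """Subunit-exchange verdict from a mixed-isotope experiment.

    ``mixed_matches``: matches from oligomers mixed (14N + 15N pools) and
    *then* crosslinked; ``control_matches``: pools crosslinked separately and
    mixed afterwards.  Exchange is demonstrated when hybrid crosslinks are
    present in the mixed condition and absent in the control.

    A spectrum's identification is its best explanation, so only the
    top-ranked match per spectrum is considered (and, by default, only
    matches passing the acceptance flags) - lower-ranked alternative
    candidates whose nitrogen count happens to compensate an isotope shift
    would otherwise masquerade as hybrids.
    """
    if not labeling_enabled:
        raise ValueError("hybrid detection requires 14N/15N labelling to be enabled")

    def pick(ms):
        top = best_matches(ms).values()
        return [m for m in top if m.accepted or not accepted_only]

    hm = _hybrids(pick(mixed_matches))
    hc = _hybrids(pick(control_matches))
    return HybridVerdict(exchange=bool(hm) and not hc, hybrids_mixed=hm,
                         hybrids_control=hc)


# ---------------------------------------------------------------------------
# I/O

def read_mgf(text: str) -> list[SpectrumRecord]:
    """Parse MGF text (TITLE, PEPMASS, CHARGE, peak lines)."""
    out = []
    with _mgf.MGF(io.StringIO(text)) as reader:
        for i, s in enumerate(reader):
            params = s.get("params", {})
            charge_list = params.get("charge")
            charge = int(charge_list[0]) if charge_list else None
            pepmass = params.get("pepmass", (None,))[0]
            if pepmass is None:
                warnings.warn(f"spectrum {i} has no PEPMASS; skipped")
                continue
            out.append(SpectrumRecord(
                params.get("title", f"scan_{i}"), float(pepmass), charge,
                s["m/z array"], s["intensity array"],
            ))
    return out


def write_mgf(spectra: Sequence[SpectrumRecord]) -> str:
    entries = []
    for s in spectra:
        params = {"title": s.title, "pepmass": s.precursor_mz}
        if s.charge is not None:
            params["charge"] = s.charge
        entries.append({"params": params, "m/z array": s.mz,
                        "intensity array": s.intensity})
    buf = io.StringIO()
    _mgf.write(entries, buf)
    return buf.getvalue()


def read_fasta(text: str) -> dict[str, str]:
    """FASTA text -> {record id: sequence} (Biopython-backed)."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError("no FASTA records found")
    return out


def matches_to_frame(matches: Sequence[CandidateMatch]) -> pd.DataFrame:
    """Flat TSV-ready report of search results."""
    rows = []
    for m in matches:
        c = m.candidate
        if c.kind == "crosslink":
            assert c.pair is not None
            peps = f"{c.pair.peptide_a.sequence} + {c.pair.peptide_b.sequence}"
            positions = f"{c.pair.link_pos_a}-{c.pair.link_pos_b}"
            linker = c.pair.linker.name
        else:
            assert c.peptide is not None
            peps = c.peptide.sequence
            positions = str(c.peptide.modifications[-1].site + c.peptide.start - 1)
            linker = c.peptide.modifications[-1].linker.name
        rows.append({
            "spectrum": m.spectrum_id, "candidate": c.candidate_id, "kind": c.kind,
            "peptides": peps, "positions": positions, "linker": linker,
            "isotope_state": m.isotope_state, "ppm": m.ppm, "score": m.score,
            "both_peptides": m.both_peptides,
            "unexplained_fraction": m.unexplained_fraction,
            "accepted": m.accepted,
        })
    return pd.DataFrame(rows)
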