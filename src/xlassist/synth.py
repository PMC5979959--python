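"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its arguments (same seed, same output),
so downstream recovery tests are self-contained: toy Calpha structures and
Cn homo-oligomers with known lysine-lysine distances, decoy model ensembles
around a known true structure, simulated crosslink MS/MS spectra (with
deadend/looplink/isotope-hybrid variants and noise peaks), mixed-isotope
subunit-exchange experiments, and noisy sphere scattering curves with known
radius of gyration, volume and maximum dimension.

What is emulated - and what is not: spectra have exact b/y fragment
positions with Gaussian m/z jitter and exponential-intensity uniform-m/z
noise peaks, but no isotope envelopes, charge-state distributions or LC
elution; scattering curves are ideal homogeneous spheres with multiplicative
Gaussian noise, not SEC-fractionated heterogeneous mixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import BS3, CrosslinkedPair, CrosslinkerDef, PeptideSpec, mass_to_mz, pair_mass
from .saxs import SAXSCurve
from .structmap import CrosslinkConstraint, StructureModel, ca_distance, structure_to_pdb
from .xlsearch import SpectrumRecord, theoretical_fragments

__all__ = [
    "SynthConfig",
    "LabelScheme",
    "make_structure",
    "make_oligomer",
    "lysine_positions",
    "sample_crosslinks",
    "make_decoys",
    "simulate_spectra",
    "simulate_exchange_experiment",
    "sphere_saxs",
]

_THREE_LETTER = {"A": "ALA", "K": "LYS", "L": "LEU", "S": "SER", "G": "GLY"}


@dataclass(frozen=True)
class LabelScheme:
    """Metabolic labelling of the subunit pool.

    ``fraction_15n``: fraction of subunits grown on 15N medium (the study
    mixed pools 1:1).  ``exchange``: True emulates mixing the pools *before*
    crosslinking (subunits scramble between oligomers, so the two peptides
    of a crosslink draw their labels independently); False emulates the
    control where pools are crosslinked separately and mixed afterwards
    (both peptides always share a label).
    """

    fraction_15n: float = 0.5
    exchange: bool = True


@dataclass(frozen=True)
class SynthConfig:
    """Bundle of generator settings; the seed is recorded in every output."""

    seed: int = 0
    n_residues: int = 80
    topology: str = "coil"
    oligomer_copies: int = 2
    oligomer_radius: float = 25.0
    crosslink_dmax: float = 25.0
    crosslink_count: int = 8
    noise_peaks: int = 50
    noise_intensity_mean: float = 300.0
    precursor_jitter_ppm: float = 3.0
    fragment_jitter_da: float = 0.01
    saxs_noise: float = 0.02
    labeling: Optional[LabelScheme] = None


def _sequence(n: int) -> str:
    # lysine every 5th residue (1-based 3, 8, 13, ...); bulk alternates A/L/S
    out = []
    for i in range(1, n + 1):
        if i % 5 == 3:
            out.append("K")
        else:
            out.append("ALS"[i % 3])
    return "".join(out)


def _helix(n: int, rise: float = 1.5, twist_deg: float = 100.0,
           radius: float = 2.3) -> np.ndarray:
    i = np.arange(n)
    theta = np.deg2rad(twist_deg) * i
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * i])


def make_structure(n_res: int, topology: str = "helix", seed: int = 0,
                   hinge_angle_deg: float = 140.0) -> StructureModel:
    """Deterministic toy Calpha structure.

    ``helix``: ideal alpha-helix (1.5 A rise, 100 deg/residue, 2.3 A radius).
    ``hairpin``: the same helix kinked at its midpoint by ``hinge_angle_deg``
    about the x axis - a hinge whose motion concentrates in the middle.
    ``coil``: self-avoiding random walk with 3.8 A steps.  Lysines sit at
    every 5th residue so crosslink sampling always has reactive sites.
    """
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    if topology == "helix":
        coords = _helix(n_res)
    elif topology == "hairpin":
        coords = _helix(n_res)
        mid = n_res // 2
        ang = np.deg2rad(hinge_angle_deg)
        R = np.array([[1, 0, 0],
                      [0, math.cos(ang), -math.sin(ang)],
                      [0, math.sin(ang), math.cos(ang)]])
        pivot = coords[mid]
        coords[mid:] = (coords[mid:] - pivot) @ R.T + pivot
    elif topology == "coil":
        # compact self-avoiding walk confined to protein-like density, so the
        # resulting contact network is globular and well connected
        step = 3.8
        r_conf = 3.0 * n_res ** (1.0 / 3.0) + 2.0
        for _restart in range(50):
            coords_l = [np.zeros(3)]
            ok = True
            for _ in range(n_res - 1):
                for _attempt in range(500):
                    d = rng.normal(size=3)
                    d *= step / np.linalg.norm(d)
                    cand = coords_l[-1] + d
                    if np.linalg.norm(cand) > r_conf:
                        continue
                    prev = np.array(coords_l[:-1]) if len(coords_l) > 1 else None
                    if prev is None or np.min(np.linalg.norm(prev - cand, axis=1)) > 3.5:
                        coords_l.append(cand)
                        break
                else:
                    ok = False
                    break
            if ok:
                break
        else:
            raise RuntimeError("self-avoiding walk failed; try another seed")
        coords = np.array(coords_l)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    seq = _sequence(n_res)
    residues = {
        i + 1: (_THREE_LETTER[seq[i]], coords[i].astype(float)) for i in range(n_res)
    }
    return StructureModel(f"synth-{topology}-n{n_res}-s{seed}", {"A": residues})


def lysine_positions(model: StructureModel, chain: Optional[str] = None) -> list[int]:
    chain = chain or model.chain_ids[0]
    return [num for num, (name, _) in model.chains[chain].items() if name == "LYS"]


def make_oligomer(monomer: StructureModel, copies: int, radius: float = 25.0,
                  symmetry: str = "Cn") -> StructureModel:
    """Cn homo-oligomer: copies rotated about the z axis at the given radius.

    Chains are labelled A, B, C, ...; a placement bringing any inter-chain
    Calpha pair closer than 2 A is rejected with the minimum feasible radius
    reported.
    """
    if copies < 2:
        raise ValueError("an oligomer needs at least 2 copies")
    if symmetry != "Cn":
        raise ValueError("only Cn (cyclic) symmetry is implemented")

    def place(r: float) -> StructureModel:
        base = monomer.coords() - monomer.coords().mean(axis=0)
        chains = {}
        for k in range(copies):
            ang = 2 * math.pi * k / copies
            R = np.array([[math.cos(ang), -math.sin(ang), 0],
                          [math.sin(ang), math.cos(ang), 0],
                          [0, 0, 1]])
            xyz = (base + np.array([r, 0.0, 0.0])) @ R.T
            cid = chr(ord("A") + k)
            src = monomer.chains[monomer.chain_ids[0]]
            chains[cid] = {
                num: (name, xyz[i]) for i, (num, (name, _)) in enumerate(src.items())
            }
        return StructureModel(f"{monomer.model_id}-C{copies}", chains)

    def min_interchain(m: StructureModel) -> float:
        best = math.inf
        cids = m.chain_ids
        for i, a in enumerate(cids):
            xa = m.coords(a)
            for b in cids[i + 1:]:
                xb = m.coords(b)
                d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1).min()
                best = min(best, d)
        return best

    olig = place(radius)
    if min_interchain(olig) < 2.0:
        r = radius
        while r < radius + 200 and min_interchain(place(r)) < 2.0:
            r += 1.0
        raise ValueError(
            f"chains clash at radius {radius} A; minimum feasible radius ~{r:.0f} A"
        )
    return olig


def sample_crosslinks(model: StructureModel, reactive: Sequence[int], dmax: float,
                      count: int, seed: int = 0,
                      ) -> tuple[list[CrosslinkConstraint], pd.DataFrame]:
    """Uniformly sampled lysine pairs with true Calpha distance <= dmax.

    Returns the constraints and a truth table (positions, true distance,
    seed).  If fewer than ``count`` pairs are eligible, all are returned
    with a warning.
    """
    if len(reactive) < 2:
        raise ValueError("need at least 2 reactive positions")
    rng = np.random.default_rng(seed)
    eligible = []
    for i, a in enumerate(reactive):
        for b in reactive[i + 1:]:
            d = ca_distance(model, a, b)
            if d <= dmax:
                eligible.append((a, b, d))
    if count == 0:
        return [], pd.DataFrame(columns=["pos_a", "pos_b", "distance", "seed"])
    if len(eligible) < count:
        import warnings

        warnings.warn(f"only {len(eligible)} eligible pairs (requested {count})")
        chosen = eligible
    else:
        idx = rng.choice(len(eligible), size=count, replace=False)
        chosen = [eligible[i] for i in sorted(idx)]
    constraints = [CrosslinkConstraint(a, b) for a, b, _ in chosen]
    truth = pd.DataFrame(
        [(a, b, d, seed) for a, b, d in chosen],
        columns=["pos_a", "pos_b", "distance", "seed"],
    )
    return constraints, truth


def make_decoys(model: StructureModel, rmsd_targets: Sequence[float], seed: int = 0,
                ) -> list[StructureModel]:
    """Decoy ensemble: Gaussian Calpha perturbations rescaled to target RMSDs.

    The unperturbed model (ground truth) is the first element.
    """
    if any(t <= 0 for t in rmsd_targets):
        raise ValueError("RMSD targets must be positive")
    rng = np.random.default_rng(seed)
    coords = model.coords()
    out = [StructureModel(f"{model.model_id}-true", dict(model.chains))]
    for j, target in enumerate(rmsd_targets, start=1):
        pert = rng.normal(size=coords.shape)
        pert *= target / math.sqrt(np.mean(np.sum(pert**2, axis=1)))
        decoy = model.with_coords(coords + pert)
        decoy.model_id = f"{model.model_id}-decoy{j}-rmsd{target:g}"
        out.append(decoy)
    return out


def _pair_with_labels(pair: CrosslinkedPair, label_a: str, label_b: str) -> CrosslinkedPair:
    return CrosslinkedPair(
        pair.peptide_a.with_label(label_a), pair.peptide_b.with_label(label_b),
        pair.link_pos_a, pair.link_pos_b, pair.linker,
    )


def simulate_spectra(pairs: Sequence[CrosslinkedPair],
                     seed: int = 0,
                     noise_peaks: int = 50,
                     noise_intensity_mean: float = 300.0,
                     base_intensity: float = 5000.0,
                     precursor_jitter_ppm: float = 3.0,
                     fragment_jitter_da: float = 0.01,
                     charge: int = 4,
                     labeling: Optional[LabelScheme] = None,
                     ) -> tuple[list[SpectrumRecord], pd.DataFrame]:
    """One simulated CID spectrum per crosslinked pair, plus a truth table.

    Fragment peaks are the theoretical b/y ions (both peptides, charges 1-2)
    with Gaussian m/z jitter; noise peaks have uniform m/z and
    exponential-distributed intensity.  With a :class:`LabelScheme`, isotope
    states are drawn per the scheme (independent per peptide when
    ``exchange`` is True, identical otherwise).
    """
    rng = np.random.default_rng(seed)
    spectra = []
    truth_rows = []
    for i, pair in enumerate(pairs):
        if labeling is None:
            la = lb = "14N"
        elif labeling.exchange:
            la = "15N" if rng.random() < labeling.fraction_15n else "14N"
            lb = "15N" if rng.random() < labeling.fraction_15n else "14N"
        else:
            la = lb = "15N" if rng.random() < labeling.fraction_15n else "14N"
        lp = _pair_with_labels(pair, la, lb)
        mass = pair_mass(lp)
        mz0 = mass_to_mz(mass, charge)
        mz0 *= 1.0 + rng.normal(0.0, precursor_jitter_ppm) * 1e-6
        frags = theoretical_fragments(lp, max_fragment_charge=2)
        # centroided spectra carry one peak per m/z: merge coincident ions
        fmz = np.unique(np.round([f.mz for f in frags], 4))
        fmz = fmz + rng.normal(0.0, fragment_jitter_da, size=fmz.shape)
        fint = base_intensity * rng.uniform(0.3, 1.0, size=fmz.shape)
        if noise_peaks > 0:
            nmz = rng.uniform(150.0, max(float(fmz.max()), mz0) + 100.0, size=noise_peaks)
            nint = rng.exponential(noise_intensity_mean, size=noise_peaks)
            fmz = np.concatenate([fmz, nmz])
            fint = np.concatenate([fint, nint])
        title = f"synthXL_scan_{i}_seed{seed}"
        spectra.append(SpectrumRecord(title, mz0, charge, fmz, fint))
        truth_rows.append({
            "scan": title,
            "peptide_a": pair.peptide_a.sequence, "peptide_b": pair.peptide_b.sequence,
            "pos_a": pair.link_pos_a, "pos_b": pair.link_pos_b,
            "label_a": la, "label_b": lb,
            "isotope_state": f"{la[:2]}/{lb[:2]}",
            "neutral_mass": mass, "precursor_mz": mz0, "charge": charge,
            "seed": seed,
        })
    return spectra, pd.DataFrame(truth_rows)


def simulate_exchange_experiment(pairs: Sequence[CrosslinkedPair], exchange: bool,
                                 seed: int = 0, **kwargs,
                                 ) -> tuple[list[SpectrumRecord], pd.DataFrame]:
    """Mixed-isotope experiment: 1:1 14N/15N pools, mixed before (exchange)
    or after (control) crosslinking."""
    scheme = LabelScheme(fraction_15n=0.5, exchange=exchange)
    return simulate_spectra(pairs, seed=seed, labeling=scheme, **kwargs)


def sphere_saxs(radius: float, i0: float, q: np.ndarray, noise: float = 0.0,
                seed: int = 0, q_unit: str = "A^-1") -> SAXSCurve:
    """Scattering of a homogeneous sphere with multiplicative Gaussian noise.

    ``I(q) = I0 [3 (sin qR - qR cos qR) / (qR)^3]^2``; the sigma column is
    ``max(noise, 0.01) * I``.  With zero noise the curve is bit-exact per
    grid.  ``radius`` is in the length unit matching ``q_unit``.
    """
    if radius <= 0 or i0 <= 0:
        raise ValueError("radius and I0 must be positive")
    q = np.asarray(q, dtype=float)
    u = q * radius
    ff = np.ones_like(u)
    nz = u != 0
    ff[nz] = 3.0 * (np.sin(u[nz]) - u[nz] * np.cos(u[nz])) / u[nz] ** 3
    I = i0 * ff**2
    if noise > 0:
        rng = np.random.default_rng(seed)
        I = I * (1.0 + noise * rng.normal(size=I.shape))
    sigma = np.maximum(noise, 0.01) * np.abs(i0 * ff**2)
    sigma = np.maximum(sigma, 1e-12 * i0)
    return SAXSCurve(q, I, sigma, q_unit)
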