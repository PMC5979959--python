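"""Published DNAJB6 reference data used as pipeline inputs.

The study that motivates this package printed its crosslink tables, the
five-model Calpha-Calpha distance matrix used for monomer model selection, and
the SEC-SAXS size table.  Those printed values are *data*, fed into the same
operations a user would run on fresh measurements; they are transcribed here
so the worked examples and the reproduction script need no external files.

Residue numbering is 1-based in the DNAJB6 isoform-B sequence (241 residues:
NTD 1-71, disordered middle domain 72-189, CTD 190-241).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "AB42_SEQUENCE",
    "DNAJB6_MONOMER_KDA",
    "EM_PARTICLE_KDA",
    "DNAJB6_DOMAINS",
    "monomer_interdomain_distances",
    "monomer_intradomain_distances",
    "sec_saxs_table",
    "oligomer_crosslinks",
    "ab42_crosslinks",
]

#: Amyloid-beta 1-42 peptide sequence (reactive amines: N-terminus, K16, K28).
AB42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

#: Monomer mass of DNAJB6 isoform B, kDa.
DNAJB6_MONOMER_KDA = 26.9

#: Oligomer particle mass from non-denaturing PAGE of the EM fraction, kDa.
EM_PARTICLE_KDA = 540.0

#: Domain boundaries of the DNAJB6 monomer (1-based, inclusive).
DNAJB6_DOMAINS = {"NTD": (1, 71), "middle": (72, 189), "CTD": (190, 241)}


def monomer_interdomain_distances() -> pd.DataFrame:
    """Inter-domain crosslink Calpha-Calpha distances (angstrom) in the five
    candidate monomer homology models.

    These four NTD-CTD crosslinks discriminate between the models; the
    intra-domain ones do not (each domain is small enough that every lysine
    pair is within crosslinking range in all five models).  The published
    table prints "K296" for the ALKW peptide; ALKW spans residues 27-30, so
    the position is K29 (typographical error in the source).
    """
    rows = [
        # lys_a, lys_b, peptides, linker, model 1..5 distances
        (196, 29, "SISTSTKMVNGR + ALKW", "BS3", 66.6, 34.4, 37.3, 44.5, 22.4),
        (225, 21, "KSLTINGK + KAYRK", "BS2G", 77.9, 28.1, 45.1, 44.6, 32.8),
        (225, 60, "VEVEEDGQLKSL + EVLSDAKK", "BS2G", 58.2, 46.9, 55.3, 50.5, 36.2),
        (225, 70, "KSLTINGK + DKYGKEGL", "BS2G", 51.8, 56.2, 50.5, 47.7, 28.7),
    ]
    return pd.DataFrame(
        rows,
        columns=["lys_a", "lys_b", "peptides", "linker",
                 "model_1", "model_2", "model_3", "model_4", "model_5"],
    )


def monomer_intradomain_distances() -> pd.DataFrame:
    """Intra-domain crosslink distances (angstrom) in the five monomer models."""
    rows = [
        (20, 25, "HASPEDIKKAYR + KLALK", "BS3", 8.7, 8.7, 8.7, 8.7, 8.7),
        (21, 25, "KAYR + KLALK", "BS3", 6.1, 6.0, 6.1, 6.1, 6.1),
        (34, 25, "WHPDKNPENK + KLALK", "BS3", 11.9, 11.9, 11.9, 12.0, 11.9),
        (60, 67, "QVAEAYEVLSDAKK + DIYDKYGK", "BS3", 10.5, 10.5, 10.5, 10.4, 10.7),
    ]
    return pd.DataFrame(
        rows,
        columns=["lys_a", "lys_b", "peptides", "linker",
                 "model_1", "model_2", "model_3", "model_4", "model_5"],
    )


def sec_saxs_table() -> pd.DataFrame:
    """SEC-SAXS size parameters for the six DNAJB6 oligomer sub-populations.

    ``rg_nm``/``dmax_nm`` from the P(r) analysis, ``vp_nm3`` the Porod volume,
    ``mwp_kda`` = Vp/1.6, ``mwa_kda`` the ab-initio excluded-volume mass
    (volume/2), ``subunits`` = round(MWp / 26.9 kDa) as published.
    """
    rows = [
        ("fraction_1", 8.73, 29.6, 2368, 1480, 1450, 55),
        ("fraction_2", 8.50, 29.4, 2114, 1321, 1240, 49),
        ("fraction_3", 7.70, 27.5, 1849, 1156, 1090, 43),
        ("fraction_4", 7.43, 26.6, 1669, 1043, 979, 39),
        ("fraction_5", 6.72, 22.5, 1523, 952, 856, 35),
        ("fraction_6", 6.88, 22.2, 1470, 919, 838, 34),
    ]
    return pd.DataFrame(
        rows,
        columns=["sample", "rg_nm", "dmax_nm", "vp_nm3", "mwp_kda", "mwa_kda", "subunits"],
    )


def oligomer_crosslinks() -> pd.DataFrame:
    """DNAJB6-DNAJB6 crosslinks detected in unfractionated (oligomeric) samples.

    ``distance_a`` is the Calpha-Calpha distance on the selected monomer model
    (NaN for same-to-same-residue crosslinks, which have no intra-subunit
    realization and must be inter-subunit).  ``hybrid_verified`` marks
    crosslinks additionally observed as 14N-15N hybrids in the mixed-isotope
    experiment.
    """
    rows = [
        (3101.577, 3, "HASPEDIKKAYR + QVAEAYEVLSDAKK", 20, 60, 16.6, False),
        (1708.898, 3, "HASPEDIKK + SDAKK", 20, 60, 16.6, False),
        (2012.068, 3, "HASPEDIKK + KSISTSTK", 20, 189, 36.0, False),
        (1750.981, 3, "HASPEDIKK + KITTK", 20, 202, 29.6, False),
        (2532.388, 3, "HASPEDIKK + SLTINGKEQLL", 20, 232, 47.2, False),
        (2587.334, 4, "WHPDKNPENKEEAER + KLALK", 34, 25, 12.0, False),
        (2899.498, 4, "HPDKNPENKEEAER + KITTKR", 34, 202, 16.5, False),
        (2116.153, 3, "KQVAEAY + TINGKEQLL", 47, 232, 36.4, False),
        (2154.108, 3, "EVLSDAKKR + DIYDKY", 60, 67, 11.0, False),
        (2275.082, 3, "GKEGLNGGGGGGSHF + KQVAEAY", 70, 47, 21.6, False),
        (2439.121, 3, "GKEGLNGGGGGGSHF + DIYDKY", 70, 67, 5.4, False),
        (2812.348, 3, "GKEGLNGGGGGGSHF + VEVEEDGQLKSL", 70, 225, 28.3, False),
        (1839.014, 4, "KSISTSTK + KSISTSTK", 189, 189, None, True),
        (2506.276, 3, "VEVEEDGQLKSL + HASPEDIKK", 225, 20, 33.1, False),
        (3360.603, 3, "VEVEEDGQLKSL + WHPDKNPENKEEAER", 225, 34, 25.4, False),
        (2371.237, 3, "VEVEEDGQLKSL + EVLSDAKK", 225, 60, 36.8, False),
        (2483.232, 3, "VEVEEDGQLKSL + DIYDGYGK", 225, 67, 31.7, False),
        (2492.265, 3, "VEVEEDGQLKSL + SISTSTKM", 225, 196, 14.5, False),
        (2072.121, 3, "VEVEEDGQLKSL + KITTK", 225, 202, 12.3, False),
        (2853.531, 3, "VEVEEDGQLKSL + SLTINGKEQLL", 225, 232, 16.1, False),
        (2309.220, 3, "TINGKEQLLR + DIYDKYGK", 232, 67, 40.7, False),
        (1198.116, 3, "TINGKEQLL + KITTK", 232, 202, 25.2, False),
        (2679.516, 3, "SLTINGKEQLL + TINGKEQLLR", 232, 232, None, True),
    ]
    return pd.DataFrame(
        rows,
        columns=["precursor_mass", "charge", "peptides", "lys_a", "lys_b",
                 "distance_a", "hybrid_verified"],
    )


def ab42_crosslinks() -> pd.DataFrame:
    """Crosslinks between the amyloid-beta 1-42 peptide and DNAJB6.

    ``lys_a`` indexes the Aβ42 sequence, ``lys_b`` DNAJB6.  Only the two
    lysine side chains of Aβ42 crosslinked; its N-terminal alpha-amine did
    not, despite being crosslinker-reactive.
    """
    rows = [
        (2437.218, 3, "HDSGYEVHHQKL + KSISTSTK", 16, 189),
        (2384.301, 3, "EVHHQKL + VEVEEDGQLKSL", 16, 225),
        (2348.265, 3, "FAEDVGSNKGAIIGLM + KITTK", 28, 202),
        (3129.674, 3, "FAEDVGSNKGAIIGLM + SLTINGKEQLL", 28, 232),
    ]
    return pd.DataFrame(
        rows,
        columns=["precursor_mass", "charge", "peptides", "lys_a", "lys_b"],
    )
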