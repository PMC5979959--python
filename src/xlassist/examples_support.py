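"""Small shared builders for examples, the CLI simulator and tests.

These construct a toy lysine-rich protein, digest it, and draw crosslinked
peptide pairs from the candidate space - the standard starting point for
search round-trip experiments.
"""

from __future__ import annotations

import numpy as np

from .chem import BS3, CrosslinkedPair, CrosslinkerDef
from .xlsearch import SearchSettings, digest, enumerate_candidates

#: A 72-residue synthetic test protein: tryptic/chymotryptic sites and
#: internal lysines spread over the sequence.
TOY_PROTEIN = (
    "MSAKELGDTVKAYSPQNKGLIDEAKSMVTRPEGKAHDLFSNKTVGERAKQLWDSIKPMEYAKGNTRVLDKSA"
)


def toy_crosslink_pairs(n: int, seed: int = 0,
                        linker: CrosslinkerDef = BS3,
                        protein: str = TOY_PROTEIN) -> list[CrosslinkedPair]:
    """Draw ``n`` distinct crosslinked-pair candidates from the toy digest."""
    settings = SearchSettings()
    peptides = digest(protein, settings, protein_id="toy")
    cands = [
        c for c in enumerate_candidates(peptides, linker, settings,
                                        protein_lengths={"toy": len(protein)})
        if c.kind == "crosslink"
    ]
    if not cands:
        raise RuntimeError("no crosslink candidates in toy digest")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cands), size=min(n, len(cands)), replace=False)
    return [cands[i].pair for i in sorted(idx)]
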