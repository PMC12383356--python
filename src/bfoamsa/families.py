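"""Synthetic homologous sequence families.

Every optimizer and analysis operation in this package is exercised on
families produced here: one random ancestor, and descendants derived by
independent per-site substitutions plus geometric-length insertions and
deletions.  Descendant lengths therefore vary, as in real homolog sets.
This is deliberately *not* a phylogenetic simulator — there is no tree and
no rate heterogeneity — just enough shared signal that a gap-placement
optimizer has something to find.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .seqio import SequenceRecord

__all__ = ["FamilySpec", "generate_family", "load_bundled_family", "BUNDLED_FAMILIES"]

_LETTERS = {"dna": "ACGT", "protein": "ACDEFGHIKLMNPQRSTVWY"}

#: Small frozen families shipped with the package (synthetic, see data/).
BUNDLED_FAMILIES = ("dna_small", "protein_small", "protein_divergent")


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic family.

    Defaults give a compact test family: 4 protein descendants of a
    60-residue ancestor with 5% substitutions and 2% indel events of
    geometric length (truncated at 3).
    """

    n_sequences: int = 4
    ancestor_length: int = 60
    alphabet: str = "protein"
    substitution_rate: float = 0.05
    indel_rate: float = 0.02
    max_indel_len: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise ValueError("n_sequences must be >= 2")
        if self.ancestor_length < 1:
            raise ValueError("ancestor_length must be >= 1")
        if self.alphabet not in _LETTERS:
            raise ValueError(f"alphabet must be one of {sorted(_LETTERS)}")
        for name in ("substitution_rate", "indel_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.max_indel_len < 1:
            raise ValueError("max_indel_len must be >= 1")


def _descend(ancestor: str, spec: FamilySpec, rng: np.random.Generator) -> str:
    """One descendant: per-site substitutions + geometric indels."""
    letters = _LETTERS[spec.alphabet]
    out: list[str] = []
    skip = 0
    for ch in ancestor:
        if skip:
            skip -= 1
            continue
        if spec.indel_rate and rng.random() < spec.indel_rate:
            length = min(int(rng.geometric(0.5)), spec.max_indel_len)
            if rng.random() < 0.5:
                skip = length - 1  # deletion: drop this site and length-1 more
                continue
            out.extend(rng.choice(list(letters), size=length))  # insertion
        if spec.substitution_rate and rng.random() < spec.substitution_rate:
            ch = str(rng.choice(list(letters)))
        out.append(ch)
    return "".join(out) or str(rng.choice(list(letters)))


def generate_family(spec: FamilySpec) -> list[SequenceRecord]:
    """Generate ``n_sequences`` homologous descendants of a random ancestor."""
    rng = np.random.default_rng(spec.seed)
    letters = list(_LETTERS[spec.alphabet])
    ancestor = "".join(rng.choice(letters, size=spec.ancestor_length))
    return [
        SequenceRecord(
            id=f"seq{i + 1}",
            residues=_descend(ancestor, spec, rng),
            description=f"synthetic {spec.alphabet} descendant (seed={spec.seed})",
        )
        for i in range(spec.n_sequences)
    ]


def load_bundled_family(name: str) -> list[SequenceRecord]:
    """Load one of the frozen synthetic families shipped under ``data/``."""
    from .seqio import read_fasta

    if name not in BUNDLED_FAMILIES:
        raise ValueError(f"unknown bundled family {name!r}; options: {BUNDLED_FAMILIES}")
    ref = resources.files("bfoamsa").joinpath("data", f"{name}.fasta")
    with resources.as_file(ref) as path:
        return read_fasta(path)
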