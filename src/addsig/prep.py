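"""Genome cleaning, fragmentation and fragment sampling.

Raw genome records are reduced to the {A, C, G, T} alphabet (every other
letter, e.g. N or IUPAC ambiguity codes, is dropped; case is folded), then cut
into successive non-overlapping fragments of a fixed length (default 150 kbp);
a final portion shorter than the fragment length is discarded.  Fragment
coordinates are 1-based and refer to the *cleaned* sequence.

Chromosome-level assemblies contribute up to 20 randomly sampled fragments per
chromosome; contig/scaffold-level assemblies contribute the first fragment of
each of the 500 longest contigs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .fcgr import DnaSequence

__all__ = [
    "GenomeRecord",
    "FragmentSet",
    "clean_sequence",
    "fragment_genome",
    "sample_fragments",
    "select_contig_fragments",
]

DEFAULT_FRAGMENT_LENGTH = 150_000
DEFAULT_FRAGMENTS_PER_UNIT = 20
DEFAULT_MAX_CONTIGS = 500

# keep ACGT (either case, folded to upper), delete every other character
_NON_ACGT = re.compile(r"[^ACGTacgt]+")


@dataclass
class GenomeRecord:
    """A genome as a list of sequence units (chromosomes or contigs/scaffolds)."""

    organism: str
    units: list[DnaSequence]
    assembly_level: str = "chromosome"  # or "contig_scaffold"

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("a genome record needs at least one unit")
        ids = [u.id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValueError("unit ids must be unique within a genome")
        if self.assembly_level not in ("chromosome", "contig_scaffold"):
            raise ValueError("assembly_level must be 'chromosome' or 'contig_scaffold'")


@dataclass
class FragmentSet:
    """Equal-length genome fragments with per-fragment provenance."""

    fragments: list[DnaSequence]
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH

    def __post_init__(self) -> None:
        for f in self.fragments:
            if len(f) != self.fragment_length:
                raise ValueError(
                    f"fragment {f.id!r} has length {len(f)}, expected {self.fragment_length}"
                )

    def __len__(self) -> int:
        return len(self.fragments)


def clean_sequence(raw: str, id: str = "", provenance: dict | None = None) -> DnaSequence:
    """Keep only A/C/G/T characters (case-folded), preserving order."""
    return DnaSequence(_NON_ACGT.sub("", raw).upper(), id=id, provenance=provenance)


def fragment_genome(s: DnaSequence, L: int = DEFAULT_FRAGMENT_LENGTH) -> FragmentSet:
    """Cut a cleaned sequence into floor(|s|/L) consecutive L-bp fragments.

    Fragment i (1-based) covers cleaned positions [(i-1)*L + 1, i*L]; the tail
    shorter than L is not included.
    """
    if L < 1:
        raise ValueError("fragment length must be >= 1")
    n = len(s) // L
    frags = []
    for i in range(n):
        start = i * L  # 0-based
        frags.append(
            DnaSequence(
                s.residues[start : start + L],
                id=f"{s.id}|frag{i + 1}",
                provenance={
                    "unit": s.id,
                    "fragment_index": i + 1,
                    "start": start + 1,  # 1-based on the cleaned sequence
                },
            )
        )
    return FragmentSet(frags, fragment_length=L)


def sample_fragments(
    fs: FragmentSet,
    max_per_unit: int = DEFAULT_FRAGMENTS_PER_UNIT,
    seed: "int | np.random.Generator" = 0,
) -> FragmentSet:
    """Uniformly sample up to ``max_per_unit`` fragments per unit, without replacement.

    Units with fewer fragments contribute all of them.  Selection order within
    a unit follows the original fragment order; reproducible per seed.
    """
    if max_per_unit < 1:
        raise ValueError("max_per_unit must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_unit: dict[str, list[DnaSequence]] = {}
    order: list[str] = []
    for f in fs.fragments:
        unit = (f.provenance or {}).get("unit", "")
        if unit not in by_unit:
            by_unit[unit] = []
            order.append(unit)
        by_unit[unit].append(f)
    chosen: list[DnaSequence] = []
    for unit in order:
        group = by_unit[unit]
        if len(group) <= max_per_unit:
            chosen.extend(group)
        else:
            idx = np.sort(rng.choice(len(group), size=max_per_unit, replace=False))
            chosen.extend(group[i] for i in idx)
    return FragmentSet(chosen, fragment_length=fs.fragment_length)


def select_contig_fragments(
    g: GenomeRecord,
    max_contigs: int = DEFAULT_MAX_CONTIGS,
    L: int = DEFAULT_FRAGMENT_LENGTH,
) -> FragmentSet:
    """First L-bp fragment of each of the ``max_contigs`` longest contigs.

    Contigs are sorted by descending cleaned length (ties broken by unit id);
    contigs shorter than L contribute nothing.
    """
    if g.assembly_level != "contig_scaffold":
        raise ValueError("select_contig_fragments applies to contig/scaffold assemblies")
    ranked = sorted(g.units, key=lambda u: (-len(u), u.id))[:max_contigs]
    frags = []
    for u in ranked:
        if len(u) >= L:
            frags.append(
                DnaSequence(
                    u.residues[:L],
                    id=f"{u.id}|frag1",
                    provenance={"unit": u.id, "fragment_index": 1, "start": 1},
                )
            )
    return FragmentSet(frags, fragment_length=L)
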