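"""Ground-truth synthetic spectra for testing and calibration.

A *block molecule* is a linear chain of mass blocks; fragmentation is
modeled as every non-empty contiguous run of blocks yielding one
charged fragment (run mass + applicable modifier deltas + adduct mass).
Chemical modifications are per-block mass deltas: two molecules sharing
a block skeleton but differing by modifiers produce spectra whose
interspectral m/z differences repeat systematically (the modifier
masses and their sums), exactly the structure the similarity matrix is
built to detect.  Unrelated null spectra are uniform random m/z lists
with a minimum spacing that avoids accidental difference structure.

Defaults model small-molecule MS/MS in positive mode: six blocks of
60–180 Da (fragment-rich spectra of ~21 ions, comparable to library
spectra of mid-sized metabolites), protonated adduct, and one or two
modifiers drawn from common elemental-change deltas (CH2, O, H2, C2H4,
H2O, CH2O).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .spectra_io import FragmentationSpectrum, canonicalize

__all__ = [
    "PROTON_MASS",
    "COMMON_MODIFIER_MASSES",
    "BlockMolecule",
    "GroundTruthPair",
    "enumerate_fragments",
    "make_related_pair",
    "random_spectrum",
    "random_block_molecule",
    "related_pairs",
    "unrelated_pairs",
]

PROTON_MASS = 1.007276

# frequent small-molecule modification masses (Da): CH2, O, H2, C2H4, H2O, CH2O
COMMON_MODIFIER_MASSES = (14.01565, 15.99491, 2.01565, 28.03130, 18.01056, 30.01057)

DEFAULT_N_BLOCKS = 6
DEFAULT_BLOCK_MASS_RANGE = (60.0, 180.0)


@dataclass(frozen=True)
class BlockMolecule:
    """A linear chain of mass blocks with optional per-block modifiers."""

    block_masses: tuple[float, ...]
    modifier_masses: Mapping[int, float] = field(default_factory=dict)
    charge_adduct_mass: float = PROTON_MASS

    def __post_init__(self):
        if len(self.block_masses) < 2:
            raise ParameterError("a block molecule needs at least 2 blocks")
        if any(b <= 0 for b in self.block_masses):
            raise ParameterError("block masses must be positive")
        for idx in self.modifier_masses:
            if not 0 <= idx < len(self.block_masses):
                raise ParameterError(f"modifier index {idx} outside block range")

    def with_modifiers(self, modifiers: Mapping[int, float]) -> "BlockMolecule":
        merged = dict(self.modifier_masses)
        for idx, delta in modifiers.items():
            merged[idx] = merged.get(idx, 0.0) + delta
        return BlockMolecule(
            block_masses=self.block_masses,
            modifier_masses=merged,
            charge_adduct_mass=self.charge_adduct_mass,
        )


@dataclass(frozen=True)
class GroundTruthPair:
    """A spectrum pair with known relatedness.

    When related, ``shared_fragment_map`` maps fragment indices of
    ``spectrum_a`` to the corresponding (same contiguous block run)
    fragment indices of ``spectrum_b``.
    """

    spectrum_a: FragmentationSpectrum
    spectrum_b: FragmentationSpectrum
    related: bool
    shared_fragment_map: Mapping[int, int] = field(default_factory=dict)


def _run_masses(mol: BlockMolecule) -> dict[tuple[int, int], float]:
    """Fragment mass of every contiguous block run (i..j inclusive)."""
    blocks = mol.block_masses
    k = len(blocks)
    out = {}
    for i in range(k):
        total = 0.0
        for j in range(i, k):
            total += blocks[j] + mol.modifier_masses.get(j, 0.0)
            out[(i, j)] = total + mol.charge_adduct_mass
    return out


def enumerate_fragments(mol: BlockMolecule, spectrum_id: str = "synthetic") -> FragmentationSpectrum:
    """Spectrum of all contiguous-run fragments of a block molecule.

    k blocks give k(k+1)/2 runs; fragments whose masses collide are
    merged, so the spectrum has at most that many peaks.  The precursor
    is the full-chain fragment (all blocks plus adduct).
    """
    masses = _run_masses(mol)
    values = np.array(sorted(masses.values()))
    if np.any(values <= 0):
        raise ParameterError("a fragment mass is nonpositive; check modifier deltas")
    unique = np.unique(values)
    precursor = masses[(0, len(mol.block_masses) - 1)]
    spec = FragmentationSpectrum(
        spectrum_id=spectrum_id,
        precursor_mz=float(precursor),
        mz=unique,
        adduct="[M+H]+" if mol.charge_adduct_mass > 0 else "[M-H]-",
    )
    return canonicalize(spec)


def make_related_pair(
    base: BlockMolecule,
    modifiers: Mapping[int, float],
    pair_id: str = "pair",
) -> GroundTruthPair:
    """A spectrum pair from one skeleton, the second carrying modifiers."""
    modified = base.with_modifiers(modifiers)
    spec_a = enumerate_fragments(base, spectrum_id=f"{pair_id}_a")
    spec_b = enumerate_fragments(modified, spectrum_id=f"{pair_id}_b")
    runs_a = _run_masses(base)
    runs_b = _run_masses(modified)
    fragment_map = {}
    for run, mass_a in runs_a.items():
        idx_a = int(np.searchsorted(spec_a.mz, mass_a))
        idx_b = int(np.searchsorted(spec_b.mz, runs_b[run]))
        fragment_map[idx_a] = idx_b
    return GroundTruthPair(
        spectrum_a=spec_a,
        spectrum_b=spec_b,
        related=True,
        shared_fragment_map=fragment_map,
    )


def random_spectrum(
    n_fragments: int,
    mz_range: tuple[float, float] = (100.0, 900.0),
    rng=None,
    min_spacing: float = 0.02,
    spectrum_id: str = "null",
) -> FragmentationSpectrum:
    """Uniform random m/z list with enforced minimum peak spacing.

    ``min_spacing`` defaults to twice the default counting tolerance so
    that no two peaks of a null spectrum fall in the same tolerance
    window by construction.
    """
    if rng is None:
        raise ParameterError("rng is required")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if n_fragments < 1:
        raise ParameterError("n_fragments must be >= 1")
    lo, hi = mz_range
    span = hi - lo - (n_fragments - 1) * min_spacing
    if span <= 0:
        raise ParameterError("mz_range too small for the requested spacing")
    base = np.sort(rng.uniform(0.0, span, size=n_fragments))
    mz = lo + base + min_spacing * np.arange(n_fragments)
    return FragmentationSpectrum(
        spectrum_id=spectrum_id,
        precursor_mz=float(mz[-1] + PROTON_MASS),
        mz=mz,
    )


def random_block_molecule(
    rng: np.random.Generator,
    n_blocks: int = DEFAULT_N_BLOCKS,
    block_mass_range: tuple[float, float] = DEFAULT_BLOCK_MASS_RANGE,
) -> BlockMolecule:
    """A random skeleton with uniformly drawn block masses."""
    masses = rng.uniform(*block_mass_range, size=n_blocks)
    return BlockMolecule(block_masses=tuple(float(b) for b in masses))


def _random_modifiers(
    rng: np.random.Generator, n_blocks: int, n_modifiers: int
) -> dict[int, float]:
    idx = rng.choice(n_blocks, size=n_modifiers, replace=False)
    deltas = rng.choice(COMMON_MODIFIER_MASSES, size=n_modifiers, replace=True)
    return {int(i): float(d) for i, d in zip(idx, deltas)}


def related_pairs(
    n_pairs: int,
    rng,
    n_blocks: int = DEFAULT_N_BLOCKS,
    modifier_counts: Sequence[int] = (1, 2),
) -> list[GroundTruthPair]:
    """Related pairs: shared skeleton, 1–2 modifiers on distinct blocks."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = []
    for i in range(n_pairs):
        base = random_block_molecule(rng, n_blocks=n_blocks)
        n_mod = int(rng.choice(modifier_counts))
        modifiers = _random_modifiers(rng, n_blocks, n_mod)
        out.append(make_related_pair(base, modifiers, pair_id=f"related{i}"))
    return out


def unrelated_pairs(
    n_pairs: int,
    rng,
    n_fragments: int = DEFAULT_N_BLOCKS * (DEFAULT_N_BLOCKS + 1) // 2,
    mz_range: tuple[float, float] = (100.0, 900.0),
) -> list[GroundTruthPair]:
    """Null pairs: two independent uniform random spectra each."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = []
    for i in range(n_pairs):
        a = random_spectrum(n_fragments, mz_range, rng, spectrum_id=f"null{i}_a")
        b = random_spectrum(n_fragments, mz_range, rng, spectrum_id=f"null{i}_b")
        out.append(GroundTruthPair(spectrum_a=a, spectrum_b=b, related=False))
    return out
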