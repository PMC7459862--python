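"""Synthetic sequence databases with planted conserved motifs.

The generator emulates the one exploitable structure the design algorithm
relies on: a conserved locus shared by a known fraction of sequences, with
known single-base variants at known frequencies, embedded in i.i.d.
uniform-ACGT background. The manifest records exactly which sequence
carries which motif version at which coordinate, giving every downstream
stage a ground truth: the expected IUPAC consensus, the expected coverage
(carrier fractions sum), and — for paired motifs at fixed spacing — the
expected amplicon length.

Carrier counts are deterministic (half-up rounding of n·fraction) and all
randomness flows from one integer seed, so a fixed seed reproduces the
database byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import iupac
from .seq_processing import SequenceRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PairedMotif:
    """A second conserved locus downstream of the main one.

    ``spacing`` is downstream start minus upstream start on the sense
    strand; with primer lengths Lf and Lr the true amplicon length is
    ``spacing + len(consensus)`` when the downstream motif is the reverse
    complement of the reverse primer.
    """

    consensus: str
    spacing: int


@dataclass(frozen=True)
class PlantedMotifSpec:
    """One conserved locus: exact consensus plus optional 1-base variants.

    ``carrier_fraction`` of sequences receive the exact consensus;
    each ``(position, alternative base, fraction)`` in ``variant_defs``
    places the variant version in a further disjoint fraction.
    """

    consensus: str
    carrier_fraction: float = 1.0
    variant_defs: tuple[tuple[int, str, float], ...] = ()
    position: Optional[int] = None  # fixed start; None = uniform placement
    paired_motif: Optional[PairedMotif] = None

    def __post_init__(self) -> None:
        if not 0 < self.carrier_fraction <= 1:
            raise ValueError("carrier_fraction must be in (0, 1]")
        for pos, alt, frac in self.variant_defs:
            if not 0 <= pos < len(self.consensus):
                raise ValueError(f"variant position {pos} outside consensus")
            if alt == self.consensus[pos] or alt not in "ACGT":
                raise ValueError(f"bad variant base {alt!r} at {pos}")
            if not 0 < frac <= 1:
                raise ValueError("variant fraction must be in (0, 1]")

    @property
    def expected_iupac(self) -> str:
        """The degenerate consensus the designer should recover."""
        out = list(self.consensus)
        for pos, alt, _ in self.variant_defs:
            out[pos] = iupac.merge_codes(out[pos], alt)
        return "".join(out)

    @property
    def total_carrier_fraction(self) -> float:
        return self.carrier_fraction + sum(f for _, _, f in self.variant_defs)


def _n_half_up(n: int, frac: float) -> int:
    return int(n * frac + 0.5)


def generate_database(
    n_seqs: int,
    seq_len_range: tuple[int, int],
    motifs: Sequence[PlantedMotifSpec],
    seed: int,
) -> tuple[list[SequenceRecord], dict]:
    """Random database with motifs planted per spec, plus a truth manifest.

    Returns ``(records, manifest)``; the manifest maps each motif to its
    expected IUPAC string and a per-carrier record of coordinates and
    variant identity. Deterministic for a fixed seed.
    """
    lo, hi = seq_len_range
    if not 0 < lo <= hi:
        raise ValueError("invalid sequence length range")
    for spec in motifs:
        need = len(spec.consensus)
        if spec.paired_motif is not None:
            need = max(need, spec.paired_motif.spacing + len(spec.paired_motif.consensus))
        if spec.position is not None:
            need += spec.position
        if need > lo:
            raise ValueError("motif placement does not fit the shortest sequence")

    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_seqs)
    seqs = ["".join(_BASES[rng.integers(0, 4, size=L)]) for L in lengths]

    manifest: dict = {"seed": seed, "n_seqs": n_seqs, "motifs": []}
    for m_idx, spec in enumerate(motifs):
        order = rng.permutation(n_seqs)
        cursor = 0
        versions: list[tuple[str, Optional[tuple[int, str]]]] = [
            (spec.consensus, None)
        ]
        counts = [_n_half_up(n_seqs, spec.carrier_fraction)]
        for pos, alt, frac in spec.variant_defs:
            versions.append(
                (spec.consensus[:pos] + alt + spec.consensus[pos + 1 :], (pos, alt))
            )
            counts.append(_n_half_up(n_seqs, frac))
        if sum(counts) > n_seqs:
            raise ValueError("carrier fractions exceed the database size")

        carriers: dict[str, dict] = {}
        footprint = len(spec.consensus)
        if spec.paired_motif is not None:
            footprint = max(
                footprint,
                spec.paired_motif.spacing + len(spec.paired_motif.consensus),
            )
        for (version, variant), count in zip(versions, counts):
            for idx in order[cursor : cursor + count]:
                L = int(lengths[idx])
                if spec.position is not None:
                    start = spec.position
                else:
                    start = int(rng.integers(0, L - footprint + 1))
                s = seqs[idx]
                s = s[:start] + version + s[start + len(version) :]
                entry: dict = {"start": start, "variant": variant}
                if spec.paired_motif is not None:
                    p = spec.paired_motif
                    pstart = start + p.spacing
                    s = s[:pstart] + p.consensus + s[pstart + len(p.consensus) :]
                    entry["paired_start"] = pstart
                seqs[idx] = s
                carriers[f"seq{idx}"] = entry
            cursor += count

        manifest["motifs"].append(
            {
                "index": m_idx,
                "consensus": spec.consensus,
                "expected_iupac": spec.expected_iupac,
                "n_carriers": sum(counts),
                "carrier_fraction": sum(counts) / n_seqs,
                "carriers": carriers,
            }
        )

    records = [
        SequenceRecord(id=f"seq{i}", description="synthetic", seq=seqs[i])
        for i in range(n_seqs)
    ]
    return records, manifest
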