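"""Physical-map quality statistics.

Plastid contamination, band-count-to-length calibration and the
single-copy-probe consistency summary used to assess a fingerprint
physical map.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

__all__ = [
    "LibraryStats",
    "contamination_rate",
    "estimate_contig_length_kb",
    "probe_consistency",
    "ProbeReport",
]

DEFAULT_AVG_INSERT_KB = 123.0
DEFAULT_AVG_BANDS = 128.0


@dataclass(frozen=True)
class LibraryStats:
    n_clones: int
    n_fingerprinted: int
    avg_insert_kb: float
    avg_bands_per_clone: float
    organellar_contig_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_fingerprinted > self.n_clones:
            raise ValueError("n_fingerprinted cannot exceed n_clones")
        if self.avg_insert_kb <= 0 or self.avg_bands_per_clone <= 0:
            raise ValueError("averages must be > 0")


def contamination_rate(n_in_organellar_contig: int, n_fingerprinted: int) -> float:
    """Percent of fingerprinted clones in the organellar contig, rounded
    half-up to 1 decimal place."""
    if n_fingerprinted <= 0:
        raise ValueError("n_fingerprinted must be > 0")
    if not 0 <= n_in_organellar_contig <= n_fingerprinted:
        raise ValueError("need 0 <= numerator <= denominator")
    pct = Decimal(100 * n_in_organellar_contig) / Decimal(n_fingerprinted)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def estimate_contig_length_kb(
    band_count: int,
    avg_insert_kb: float = DEFAULT_AVG_INSERT_KB,
    avg_bands: float = DEFAULT_AVG_BANDS,
) -> float:
    """Rough contig length from its fingerprint band count, using the
    average-insert over average-bands calibration (128 bands ~ 123 kb)."""
    if band_count < 1:
        raise ValueError("band_count must be >= 1")
    return band_count * avg_insert_kb / avg_bands


@dataclass(frozen=True)
class ProbeReport:
    per_probe: dict[str, tuple[int, int]]  # probe -> (contig count, clone count)
    fraction_single_contig: float
    mean_clones: float
    empty_probes: tuple[str, ...]


def probe_consistency(
    probe_to_positive_clones: Mapping[str, Sequence[str]],
    clone_to_contig: Mapping[str, str],
) -> ProbeReport:
    """Per-probe contig spread of hybridization-positive clones.

    A probe is 'consistent' when all its positives map to one contig.
    Probes with no positives are reported with 0 clones and flagged.
    Raises when a positive clone has no contig assignment.
    """
    per_probe: dict[str, tuple[int, int]] = {}
    empty: list[str] = []
    for probe, clones in sorted(probe_to_positive_clones.items()):
        if not clones:
            per_probe[probe] = (0, 0)
            empty.append(probe)
            continue
        contigs = set()
        for clone in clones:
            if clone not in clone_to_contig:
                raise ValueError(f"clone '{clone}' has no contig assignment")
            contigs.add(clone_to_contig[clone])
        per_probe[probe] = (len(contigs), len(clones))
    nonempty = {p: v for p, v in per_probe.items() if v[1] > 0}
    n = len(nonempty)
    fraction = (
        sum(1 for c, _k in nonempty.values() if c == 1) / n if n else float("nan")
    )
    mean_clones = (
        sum(k for _c, k in nonempty.values()) / n if n else float("nan")
    )
    return ProbeReport(
        per_probe=per_probe,
        fraction_single_contig=fraction,
        mean_clones=mean_clones,
        empty_probes=tuple(empty),
    )
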