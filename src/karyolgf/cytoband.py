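"""Ordered genome-wide cytoband reference at the ~850-band ISCN resolution.

The reference owns the coordinate system of the Loss-Gain-Fusion encoding:
every band is identified by (chromosome, arm-prefixed ISCN label) and carries
an ordinal position from pter to qter.  Coordinates are purely ordinal -- no
base pairs, no genome build.

Band-prefix algebra follows the ISCN hierarchy: a coarse breakpoint such as
"q13" designates the whole set of 850-level sub-bands q13.1, q13.2, ...;
matching compares the digit string after the arm letter, ignoring the dot
(so "q11.2" covers q11.21 and q11.22 but not q11.1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

CHROMOSOMES = [str(c) for c in range(1, 23)] + ["X", "Y"]

_BAND_RE = re.compile(r"^([pq])(\d+(?:\.\d+)?)$")


class CytobandError(ValueError):
    """Malformed band table or unresolvable band reference."""


@dataclass(frozen=True)
class Cytoband:
    chromosome: str
    band_label: str  # arm-prefixed, e.g. "p15.1"
    order_index: int  # 0-based position pter->qter within the chromosome

    @property
    def arm(self) -> str:
        return self.band_label[0]

    @property
    def digits(self) -> str:
        """Band digits with the sub-band dot removed ("q11.21" -> "1121")."""
        return self.band_label[1:].replace(".", "")

    def __str__(self) -> str:  # e.g. "5q31.1"
        return f"{self.chromosome}{self.band_label}"


class CytobandReference:
    """Ordered collection of all cytobands with (chromosome, label) lookup."""

    def __init__(self, bands: Iterable[Cytoband]):
        self.bands: list[Cytoband] = list(bands)
        self.index: dict[tuple[str, str], int] = {}
        # global position of each band in the genome-wide order
        for pos, b in enumerate(self.bands):
            key = (b.chromosome, b.band_label)
            if key in self.index:
                raise CytobandError(f"duplicate band {b.chromosome}{b.band_label}")
            self.index[key] = pos
        self._by_chrom: dict[str, list[Cytoband]] = {c: [] for c in CHROMOSOMES}
        for b in self.bands:
            if b.chromosome not in self._by_chrom:
                raise CytobandError(f"unknown chromosome {b.chromosome!r}")
            self._by_chrom[b.chromosome].append(b)
        missing = [c for c, bs in self._by_chrom.items() if not bs]
        if missing:
            raise CytobandError(f"missing chromosome(s): {', '.join(missing)}")
        for c, bs in self._by_chrom.items():
            orders = [b.order_index for b in bs]
            if orders != sorted(orders) or len(set(orders)) != len(orders):
                raise CytobandError(f"order_index not strictly increasing on chromosome {c}")
            arms = [b.arm for b in bs]
            if arms != sorted(arms):  # "p" < "q"
                raise CytobandError(f"p-arm bands must precede q-arm bands on chromosome {c}")

    def __len__(self) -> int:
        return len(self.bands)

    def chromosome_bands(self, chromosome: str) -> list[Cytoband]:
        try:
            return self._by_chrom[chromosome]
        except KeyError:
            raise CytobandError(f"unknown chromosome {chromosome!r}") from None

    def arm_bands(self, chromosome: str, arm: str) -> list[Cytoband]:
        return [b for b in self.chromosome_bands(chromosome) if b.arm == arm]

    def position(self, chromosome: str, band_label: str) -> int:
        """Genome-wide array position of an exact band."""
        try:
            return self.index[(chromosome, band_label)]
        except KeyError:
            raise CytobandError(f"unknown band {chromosome}{band_label}") from None

    def positions(self, bands: Iterable[Cytoband]) -> list[int]:
        return [self.index[(b.chromosome, b.band_label)] for b in bands]


def load_reference(source: str | Path | None = None) -> CytobandReference:
    """Load a band table (TSV: chrom, band, order; '#' comments) into a reference.

    With no argument, loads the packaged ~850-band ideogram (868 bands).
    """
    if source is None:
        with resources.files("karyolgf.data").joinpath("cytobands_850.tsv").open() as fh:
            lines = fh.readlines()
    else:
        lines = Path(source).read_text().splitlines()
    rows = []
    header: list[str] | None = None
    for raw in lines:
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            for col in ("chrom", "band", "order"):
                if col not in header:
                    raise CytobandError(f"band table missing column {col!r}")
            continue
        rec = dict(zip(header, fields))
        label = rec["band"]
        if not _BAND_RE.match(label):
            raise CytobandError(f"malformed band label {label!r} on chromosome {rec['chrom']}")
        rows.append(Cytoband(rec["chrom"], label, int(rec["order"])))
    return CytobandReference(rows)


def expand_band_prefix(ref: CytobandReference, chromosome: str, band: str) -> list[Cytoband]:
    """All reference bands covered by a (possibly coarse) ISCN band string.

    "q13" expands to q13.1/q13.2/q13.3 at 850-band resolution; an exact leaf
    label expands to itself; a bare arm ("q") expands to the whole arm.
    Raises CytobandError when nothing matches.
    """
    band = band.strip()
    if band in ("p", "q"):
        out = ref.arm_bands(chromosome, band)
        if not out:
            raise CytobandError(f"unknown band {chromosome}{band}")
        return out
    m = _BAND_RE.match(band)
    if not m:
        raise CytobandError(f"unknown band {chromosome}{band}")
    arm, digits = m.group(1), m.group(2).replace(".", "")
    out = [
        b
        for b in ref.arm_bands(chromosome, arm)
        if b.digits == digits or b.digits.startswith(digits)
    ]
    if not out:
        raise CytobandError(f"unknown band {chromosome}{band}")
    return out


def bands_in_interval(
    ref: CytobandReference, chromosome: str, from_band: str, to_band: str
) -> list[Cytoband]:
    """All bands between two breakpoints, inclusive, in pter->qter order.

    Endpoints expand by prefix first; the interval runs from the pter-most to
    the qter-most expanded band.  Symmetric in argument order and may span the
    centromere.
    """
    a = expand_band_prefix(ref, chromosome, from_band)
    b = expand_band_prefix(ref, chromosome, to_band)
    chrom_bands = ref.chromosome_bands(chromosome)
    lo = min(x.order_index for x in a + b)
    hi = max(x.order_index for x in a + b)
    return [x for x in chrom_bands if lo <= x.order_index <= hi]
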