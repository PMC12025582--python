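"""Loss-Gain-Fusion encoding of resolved karyotypes over the cytoband reference.

Karyotypes are divided into their grammatical units (one abnormality event at
a time) and every unit is mapped independently to binary per-band indicators:
loss (L), gain (G) and fusion (F).  A clone's calls are the union over its
events, a karyotype's vector the union over its (non-donor) clones -- the
encoding records the *presence* of each kind of abnormality at a band, not a
net copy number, so multiplicities never change an already-set flag.

Per-kind semantics (see the methods note for rationale and validation):

* whole-chromosome +N / -N: gain / loss on every band of the chromosome
  (sex chromosomes included);
* del with one breakpoint: loss from the breakpoint to its arm's telomere;
  two breakpoints: loss on the enclosed interval; breakpoint bands included;
* add: loss from the breakpoint to the telomere (the replacing material is
  of unknown origin and contributes no gain); a supernumerary "+add" instead
  gains the retained proximal segment;
* dup: gain on the interval; i(q10): gain on the q arm, loss on the p arm;
* balanced t and inv: fusion at every breakpoint band, no copy change;
* dic/idic/psu dic: fusion at the breakpoints plus loss distal to each;
* der with embedded events: the recipient loses material distal to its
  breakpoint (band included); a translocated donor segment is gained with the
  donor breakpoint band excluded (only unambiguously distal material);
  embedded del/add/dup apply their own semantics; whole-arm der(A;B)(q10;q10)
  loses the complementary arms and fuses at the centromere;
* hsr: gain at the named band; markers, rings without content, dmin and
  segment-notation ("opaque") derivatives contribute nothing;
* coarse breakpoints expand to every 850-level sub-band; "?" sides are
  skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cytoband import CytobandError, CytobandReference, expand_band_prefix
from .parser import (
    GAIN,
    LOSS,
    Abnormality,
    KaryotypeRecord,
    ResolvedClone,
    classify_ploidy,
    resolve_lineage,
)

CHANNELS = ("L", "G", "F")


class LGFError(ValueError):
    pass


@dataclass
class LGFVector:
    case_id: str
    loss: np.ndarray
    gain: np.ndarray
    fusion: np.ndarray

    def channel(self, name: str) -> np.ndarray:
        return {"L": self.loss, "G": self.gain, "F": self.fusion}[name]


@dataclass
class LGFMatrix:
    cases: list
    loss: np.ndarray  # (n_cases, n_bands) uint8
    gain: np.ndarray
    fusion: np.ndarray
    reference: CytobandReference
    cohort_label: str = ""
    diagnostics: list = field(default_factory=list)

    def channel(self, name: str) -> np.ndarray:
        return {"L": self.loss, "G": self.gain, "F": self.fusion}[name]

    @property
    def n_cases(self) -> int:
        return len(self.cases)


class CopyState:
    """Accumulates the per-band L/G/F indicator flags for one clone."""

    def __init__(self, ref: CytobandReference):
        self.ref = ref
        n = len(ref)
        self.loss = np.zeros(n, dtype=np.uint8)
        self.gain = np.zeros(n, dtype=np.uint8)
        self.fusion = np.zeros(n, dtype=np.uint8)

    # --- segment helpers -------------------------------------------------
    def _expand(self, chrom: str, band: str):
        if band in ("p10", "q10"):
            return self.ref.arm_bands(chrom, band[0])
        return expand_band_prefix(self.ref, chrom, band)

    def _distal_segment(self, chrom: str, band: str, inclusive: bool):
        """Bands from a breakpoint toward the telomere of its own arm."""
        if band in ("p10", "q10"):
            return self.ref.arm_bands(chrom, band[0])
        expanded = self._expand(chrom, band)
        arm = expanded[0].arm
        arm_bands = self.ref.arm_bands(chrom, arm)
        if arm == "q":  # distal = larger order_index
            edge = (min if inclusive else max)(x.order_index for x in expanded)
            return [x for x in arm_bands if x.order_index >= edge + (0 if inclusive else 1)]
        edge = (max if inclusive else min)(x.order_index for x in expanded)
        return [x for x in arm_bands if x.order_index <= edge - (0 if inclusive else 1)]

    def _proximal_segment(self, chrom: str, band: str):
        """Complement of the strictly-distal segment (breakpoint band included)."""
        distal = {
            (x.chromosome, x.band_label)
            for x in self._distal_segment(chrom, band, inclusive=False)
        }
        return [
            x
            for x in self.ref.chromosome_bands(chrom)
            if (x.chromosome, x.band_label) not in distal
        ]

    def _interval(self, chrom: str, b1: str, b2: str):
        e1, e2 = self._expand(chrom, b1), self._expand(chrom, b2)
        lo = min(x.order_index for x in e1 + e2)
        hi = max(x.order_index for x in e1 + e2)
        return [x for x in self.ref.chromosome_bands(chrom) if lo <= x.order_index <= hi]

    # --- flag setters -----------------------------------------------------
    def mark(self, channel: str, chrom: str, bands) -> None:
        arr = {"L": self.loss, "G": self.gain, "F": self.fusion}[channel]
        for b in bands:
            arr[self.ref.position(chrom, b.band_label)] = 1

    def mark_fusion_breakpoint(self, chrom: str, band: str) -> None:
        if band in ("?",) or band.endswith("ter"):
            return
        try:
            bands = self._expand(chrom, band)
        except CytobandError:
            return
        self.mark("F", chrom, bands)


def _resolvable(chrom: str, band: str | None) -> bool:
    if chrom in ("", "?") or band is None or band == "?":
        return False
    return band in ("p10", "q10") or not band.endswith("ter")


def apply_abnormality(state: CopyState, ab: Abnormality, warn=None) -> CopyState:
    """Set the indicator flags of one abnormality event on the clone state."""
    warn = warn or (lambda m: None)
    if ab.constitutional or ab.opaque:
        return state
    kind = ab.kind
    ref = state.ref

    if kind in (GAIN, LOSS):
        chrom = ab.chromosomes[0]
        state.mark("G" if kind == GAIN else "L", chrom, ref.chromosome_bands(chrom))
        return state
    if kind in ("marker", "dmin", "ring"):
        return state

    if kind == "del":
        chrom = ab.chromosomes[0]
        bp = ab.breakpoints[0] if ab.breakpoints else []
        if len(bp) >= 2 and _resolvable(chrom, bp[0]) and _resolvable(chrom, bp[1]):
            state.mark("L", chrom, state._interval(chrom, bp[0], bp[1]))
        elif bp and _resolvable(chrom, bp[0]):
            state.mark("L", chrom, state._distal_segment(chrom, bp[0], inclusive=True))
        else:
            warn(f"unresolvable deletion breakpoint in {ab.raw_text!r}")
        return state

    if kind == "add":
        chrom = ab.chromosomes[0]
        bp = (ab.breakpoints[0] or [None])[0] if ab.breakpoints else None
        if _resolvable(chrom, bp):
            if ab.supernumerary:
                state.mark("G", chrom, state._proximal_segment(chrom, bp))
            else:
                state.mark("L", chrom, state._distal_segment(chrom, bp, inclusive=True))
        else:
            warn(f"unresolvable add breakpoint in {ab.raw_text!r}")
        return state

    if kind == "dup":
        chrom = ab.chromosomes[0]
        bp = ab.breakpoints[0] if ab.breakpoints else []
        if len(bp) >= 2 and _resolvable(chrom, bp[0]) and _resolvable(chrom, bp[1]):
            state.mark("G", chrom, state._interval(chrom, bp[0], bp[1]))
        elif bp and _resolvable(chrom, bp[0]):
            state.mark("G", chrom, state._distal_segment(chrom, bp[0], inclusive=True))
        return state

    if kind == "iso":
        chrom = ab.chromosomes[0]
        bp = (ab.breakpoints[0] or ["q10"])[0] if ab.breakpoints else "q10"
        arm = bp[0] if bp and bp[0] in ("p", "q") else "q"
        other = "p" if arm == "q" else "q"
        state.mark("G", chrom, ref.arm_bands(chrom, arm))
        if not ab.supernumerary:
            state.mark("L", chrom, ref.arm_bands(chrom, other))
        return state

    if kind in ("translocation", "inv", "ins"):
        for chrom, bps in zip(ab.chromosomes, ab.breakpoints):
            for bp in bps:
                if chrom not in ("", "?"):
                    state.mark_fusion_breakpoint(chrom, bp)
        return state

    if kind in ("dic", "idic", "psu_dic"):
        for chrom, bps in zip(ab.chromosomes, ab.breakpoints):
            bp = bps[0] if bps else None
            if not _resolvable(chrom, bp):
                continue
            state.mark_fusion_breakpoint(chrom, bp)
            state.mark("L", chrom, state._distal_segment(chrom, bp, inclusive=True))
        return state

    if kind == "hsr":
        chrom = ab.chromosomes[0]
        bp = (ab.breakpoints[0] or [None])[0] if ab.breakpoints else None
        if _resolvable(chrom, bp):
            state.mark("G", chrom, state._expand(chrom, bp))
        return state

    if kind in ("derivative", "ider"):
        _apply_derivative(state, ab, warn)
        return state

    warn(f"abnormality kind {kind!r} contributes nothing to LGF ({ab.raw_text!r})")
    return state


def _apply_derivative(state: CopyState, ab: Abnormality, warn) -> None:
    recipients = [c for c in ab.chromosomes if c not in ("", "?")]

    if not ab.embedded and len(ab.chromosomes) == 2 and ab.breakpoints:
        # whole-arm derivative, e.g. der(13;14)(q10;q10): the retained arms
        # fuse at the centromere, the complementary arms are lost
        for chrom, bps in zip(ab.chromosomes, ab.breakpoints):
            bp = bps[0] if bps else None
            if chrom in ("", "?") or bp not in ("p10", "q10"):
                continue
            kept_arm = bp[0]
            lost_arm = "p" if kept_arm == "q" else "q"
            state.mark("L", chrom, state.ref.arm_bands(chrom, lost_arm))
            kept = state.ref.arm_bands(chrom, kept_arm)
            if kept:
                state.mark_fusion_breakpoint(chrom, kept[0].band_label)
        return

    for emb in ab.embedded:
        if emb.kind == "translocation":
            if not emb.breakpoints or all(not bps for bps in emb.breakpoints):
                warn(
                    f"derivative {ab.raw_text!r}: embedded translocation without "
                    "breakpoints; no band content applied"
                )
                continue
            for chrom, bps in zip(emb.chromosomes, emb.breakpoints):
                bp = bps[0] if bps else None
                if not _resolvable(chrom, bp):
                    continue
                state.mark_fusion_breakpoint(chrom, bp)
                if chrom in recipients:
                    # recipient loses material distal to its breakpoint
                    state.mark("L", chrom, state._distal_segment(chrom, bp, inclusive=True))
                    if ab.supernumerary:
                        # an extra der also carries the recipient's proximal part
                        state.mark("G", chrom, state._proximal_segment(chrom, bp))
                else:
                    # translocated donor segment, breakpoint band excluded
                    state.mark("G", chrom, state._distal_segment(chrom, bp, inclusive=False))
        elif emb.kind in ("del", "add", "dup"):
            apply_abnormality(state, emb, warn)
        else:
            warn(f"derivative {ab.raw_text!r}: embedded {emb.kind} not mapped")


def map_karyotype(
    record: KaryotypeRecord,
    resolved: list[ResolvedClone] | None = None,
    ref: CytobandReference | None = None,
    scope: str = "all_abnormal_clones",
) -> LGFVector:
    """Encode one karyotype as a binary LGF vector (OR over in-scope clones)."""
    from .cytoband import load_reference

    if resolved is None:
        resolved = resolve_lineage(record)
    if ref is None:
        ref = load_reference()
    if scope not in ("all_abnormal_clones", "tnt_clones_only"):
        raise LGFError(f"unknown scope {scope!r}")

    n = len(ref)
    loss = np.zeros(n, dtype=np.uint8)
    gain = np.zeros(n, dtype=np.uint8)
    fusion = np.zeros(n, dtype=np.uint8)

    for rc in resolved:
        clone = rc.base
        if clone.is_donor or clone.is_normal:
            continue
        if scope == "tnt_clones_only" and classify_ploidy(clone) != "tnt":
            continue
        state = CopyState(ref)
        for ab, _mult in rc.events():
            apply_abnormality(state, ab, warn=record.warn)
        loss |= state.loss
        gain |= state.gain
        fusion |= state.fusion
    return LGFVector(case_id=record.case_id, loss=loss, gain=gain, fusion=fusion)


def build_matrix(
    records: list[KaryotypeRecord],
    ref: CytobandReference | None = None,
    scope: str = "all_abnormal_clones",
    cohort_label: str = "",
) -> LGFMatrix:
    """Stack per-case LGF vectors into a cohort matrix (unique case_ids required)."""
    from .cytoband import load_reference

    if not records:
        raise LGFError("no karyotype records supplied")
    ids = [r.case_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise LGFError(f"duplicate case_id(s): {', '.join(dupes)}")
    if ref is None:
        ref = load_reference()
    vectors = [map_karyotype(r, ref=ref, scope=scope) for r in records]
    diagnostics = [d for r in records for d in r.diagnostics]
    return LGFMatrix(
        cases=ids,
        loss=np.stack([v.loss for v in vectors]),
        gain=np.stack([v.gain for v in vectors]),
        fusion=np.stack([v.fusion for v in vectors]),
        reference=ref,
        cohort_label=cohort_label,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# TSV round-trip

def write_matrix_tsv(matrix: LGFMatrix, path) -> None:
    """Wide TSV: one row per case, one column per band x channel ("5q31.1:L")."""
    bands = [str(b) for b in matrix.reference.bands]
    with open(path, "w") as fh:
        header = ["case_id"] + [f"{b}:{ch}" for b in bands for ch in CHANNELS]
        fh.write("\t".join(header) + "\n")
        for i, case in enumerate(matrix.cases):
            row = [str(case)]
            for j in range(len(bands)):
                row.extend(str(int(matrix.channel(ch)[i, j])) for ch in CHANNELS)
            fh.write("\t".join(row) + "\n")


def write_matrix_triplets(matrix: LGFMatrix, path) -> None:
    """Sparse triplet TSV: case_id, band, channel for every set flag."""
    bands = [str(b) for b in matrix.reference.bands]
    with open(path, "w") as fh:
        fh.write("case_id\tband\tchannel\n")
        for i, case in enumerate(matrix.cases):
            for ch in CHANNELS:
                arr = matrix.channel(ch)[i]
                for j in np.nonzero(arr)[0]:
                    fh.write(f"{case}\t{bands[j]}\t{ch}\n")


def read_matrix_tsv(path, ref: CytobandReference | None = None, cohort_label: str = "") -> LGFMatrix:
    from .cytoband import load_reference

    if ref is None:
        ref = load_reference()
    bands = [str(b) for b in ref.bands]
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["case_id"] + [f"{b}:{ch}" for b in bands for ch in CHANNELS]
        if header != expected:
            raise LGFError("LGF TSV header does not match the cytoband reference")
        cases, rows = [], []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            cases.append(fields[0])
            rows.append(np.array(fields[1:], dtype=np.uint8))
    data = np.stack(rows) if rows else np.zeros((0, len(bands) * 3), dtype=np.uint8)
    return LGFMatrix(
        cases=cases,
        loss=data[:, 0::3].copy(),
        gain=data[:, 1::3].copy(),
        fusion=data[:, 2::3].copy(),
        reference=ref,
        cohort_label=cohort_label,
    )
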