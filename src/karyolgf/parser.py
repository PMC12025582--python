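"""Short-form ISCN karyotype parser with clonal-lineage resolution.

Parses karyotype strings like ``46,XX,del(5)(q13q33)[12]/77~89,idemx2,...[cp18]``
into structured clones, resolves the stemline/sideline shorthand (``sl``,
``sdl1``, ``idem``, with ``x2`` genome doubling), classifies ploidy
(tetraploid/near-tetraploid = 4n tag or 81-103 chromosomes), scores karyotype
complexity against the clone's ploidy baseline, and detects pseudodiploid
clones cytogenetically related to a T/NT clone.

Only short-form nomenclature is supported; a karyotype written in long-form
segment notation raises :class:`UnsupportedDialectError`.  Individual
derivative tokens that embed segment notation (``der(20)(20pter->...::...)``)
are retained as *opaque* derivatives: they count toward complexity but carry
no mappable band content.  ``.ish`` annotations are stripped and flagged.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .cytoband import CHROMOSOMES

SCHEMA_VERSION = "1.0"

TNT_RANGE = (81, 103)
DIPLOID_RANGE = (35, 57)

# abnormality kind names
GAIN = "gain_chromosome"
LOSS = "loss_chromosome"
STRUCTURAL_WORDS = {
    "del": "del",
    "add": "add",
    "dup": "dup",
    "trp": "dup",  # triplication: treated as a duplication-type gain
    "inv": "inv",
    "i": "iso",
    "ider": "ider",
    "idic": "idic",
    "dic": "dic",
    "psu dic": "psu_dic",
    "t": "translocation",
    "der": "derivative",
    "hsr": "hsr",
    "ins": "ins",
    "r": "ring",
}


class ParseError(ValueError):
    def __init__(self, message: str, case_id: str | None = None, offset: int | None = None):
        self.case_id = case_id
        self.offset = offset
        where = f" (case {case_id})" if case_id else ""
        at = f" at offset {offset}" if offset is not None else ""
        super().__init__(f"{message}{where}{at}")


class UnsupportedDialectError(ParseError):
    """Long-form (segment) ISCN notation outside a derivative token."""


class LineageError(ParseError):
    """Dangling sl/sdl/idem reference."""


class NotEvaluable(Exception):
    """Complexity cannot be scored (incomplete clone)."""


@dataclass
class Abnormality:
    kind: str
    chromosomes: list[str] = field(default_factory=list)
    breakpoints: list[list[str]] = field(default_factory=list)  # grouped per chromosome
    multiplicity: int = 1
    constitutional: bool = False
    raw_text: str = ""
    supernumerary: bool = False  # leading "+" on a structural token
    embedded: list["Abnormality"] = field(default_factory=list)  # der/ider content
    opaque: bool = False  # contains segment notation; unmappable
    marker_id: str | None = None

    def key(self, with_bands: bool = True) -> tuple:
        """Identity key for lineage bookkeeping and removal matching."""
        bands = tuple(tuple(g) for g in self.breakpoints) if with_bands else None
        emb = tuple(e.key(with_bands=with_bands) for e in self.embedded)
        return (self.kind, tuple(self.chromosomes), bands, self.marker_id, emb,
                self.constitutional, self.raw_text if self.opaque else None)

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "chromosomes": self.chromosomes,
            "breakpoints": self.breakpoints,
            "multiplicity": self.multiplicity,
            "raw_text": self.raw_text,
        }
        if self.constitutional:
            d["constitutional"] = True
        if self.supernumerary:
            d["supernumerary"] = True
        if self.opaque:
            d["opaque"] = True
        if self.marker_id is not None:
            d["marker_id"] = self.marker_id
        if self.embedded:
            d["embedded"] = [e.to_dict() for e in self.embedded]
        return d


@dataclass
class Removal:
    """A leading-minus reference subtracting an inherited abnormality."""

    target: Abnormality
    multiplicity: int = 1
    raw_text: str = ""


@dataclass
class Clone:
    count_min: int
    count_max: int
    ploidy_tag: int | None = None  # n-multiple from "<Nn>"
    sex_designation: str = ""
    abnormalities: list[Abnormality] = field(default_factory=list)
    removals: list[Removal] = field(default_factory=list)
    cell_count: int = 1
    composite: bool = False
    incomplete: bool = False
    lineage_ref: str | None = None  # "sl" | "idem" | "sdl<k>"
    doubling: int = 1
    is_donor: bool = False

    @property
    def is_normal(self) -> bool:
        return (
            not self.abnormalities
            and not self.removals
            and self.lineage_ref is None
            and self.count_min == self.count_max == 46
            and self.sex_designation in ("XX", "XY")
        )

    def to_dict(self) -> dict:
        return {
            "count_min": self.count_min,
            "count_max": self.count_max,
            "ploidy_tag": self.ploidy_tag,
            "sex_designation": self.sex_designation,
            "abnormalities": [a.to_dict() for a in self.abnormalities],
            "removals": [r.raw_text for r in self.removals],
            "cell_count": self.cell_count,
            "composite": self.composite,
            "incomplete": self.incomplete,
            "lineage_ref": self.lineage_ref,
            "doubling": self.doubling,
            "is_donor": self.is_donor,
            "is_normal": self.is_normal,
        }


@dataclass
class KaryotypeRecord:
    case_id: str
    clones: list[Clone]
    nonclonal_entries_skipped: int = 0
    ish_stripped: bool = False
    diagnostics: list[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.diagnostics.append(f"case {self.case_id}: {message}")

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "case_id": self.case_id,
            "clones": [c.to_dict() for c in self.clones],
            "nonclonal_entries_skipped": self.nonclonal_entries_skipped,
            "ish_stripped": self.ish_stripped,
            "diagnostics": self.diagnostics,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass
class ResolvedClone:
    base: Clone
    effective_abnormalities: dict  # Abnormality.key() -> (Abnormality, multiplicity)
    effective_ploidy_baseline: int  # 2 or 4
    shown_sex_counts: dict  # {"X": int, "Y": int} as written (post-abnormality)

    def events(self) -> list[tuple[Abnormality, int]]:
        return [(a, m) for (a, m) in self.effective_abnormalities.values() if m > 0]


# ---------------------------------------------------------------------------
# tokenization helpers

_NONCLONAL_RE = re.compile(r"^nonclonal\b.*\[\d+\]$")
_PLOIDY_ENTRY_RE = re.compile(r"^\d*n\[\d+\]$")  # e.g. "4n[1]"
_BRACKET_RE = re.compile(r"\[(cp)?(\d+)(?:[,;][^\]]*)?\]$")
_COUNT_RE = re.compile(r"^(\d+)(?:[~-](\d+))?(?:<(\d+)n>)?(.*)$")
_SEX_RE = re.compile(r"^([XY]+)(?:<(\d+)n>)?$")
_LINEAGE_RE = re.compile(r"^(sl|idem|sdl\d+)(?:x(\d+))?$")
_NUMERIC_RE = re.compile(r"^([+-])(\d+|X|Y)$")
_MAR_RE = re.compile(r"^([+-])?(?:(\d+)-(\d+))?mar(\d*)(?:x(\d+))?$")
_ANNOT_RE = re.compile(r"^([+-]?(?:\d+|X|Y))\((\d+)\)$")
_BAND_TOKEN_RE = re.compile(r"[pq](?:ter|\d+(?:\.\d+)?)|\?")


def _split_top(text: str, sep: str) -> list[str]:
    """Split on sep outside of () and []."""
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth -= 1
            if depth < 0:
                raise ParseError("unbalanced parentheses/brackets", offset=len(cur))
        if ch == sep and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if depth != 0:
        raise ParseError("unbalanced parentheses/brackets")
    parts.append("".join(cur))
    return parts


def _read_groups(text: str, pos: int) -> tuple[list[str], int]:
    """Read consecutive balanced ( ... ) groups starting at pos."""
    groups = []
    n = len(text)
    while pos < n and text[pos] == "(":
        depth, start = 0, pos
        while pos < n:
            if text[pos] == "(":
                depth += 1
            elif text[pos] == ")":
                depth -= 1
                if depth == 0:
                    break
            pos += 1
        if depth != 0:
            raise ParseError(f"unbalanced parentheses in {text!r}", offset=start)
        groups.append(text[start + 1 : pos])
        pos += 1
    return groups, pos


def _parse_bands_group(group: str) -> list[list[str]]:
    """Split a breakpoint group into per-chromosome band lists.

    "(q34;q11.2)" -> [[q34], [q11.2]]; "(p23p25)" -> [[p23, p25]];
    ":" is tolerated as a separator (transcription artifacts).
    """
    out = []
    for piece in re.split(r"[;:]", group):
        out.append(_BAND_TOKEN_RE.findall(piece))
    return out


def _is_opaque(groups: list[str]) -> bool:
    return any("::" in g or "->" in g for g in groups)


def parse_abnormality_token(token: str, record: KaryotypeRecord | None = None):
    """Parse one comma-separated clone token into an Abnormality or Removal.

    Returns None for tokens handled at clone level (``inc``).
    """
    raw = token
    warn = record.warn if record is not None else (lambda m: None)

    # per-abnormality cell-count annotations like "+X(4)" -> strip with warning
    m = _ANNOT_RE.match(token)
    if m:
        warn(f"stripped per-abnormality cell annotation in {raw!r}")
        token = m.group(1)

    m = _NUMERIC_RE.match(token)
    if m:
        sign, chrom = m.groups()
        if chrom not in CHROMOSOMES:
            raise ParseError(f"unknown chromosome in token {raw!r}")
        kind = GAIN if sign == "+" else LOSS
        return Abnormality(kind=kind, chromosomes=[chrom], raw_text=raw)

    m = _MAR_RE.match(token)
    if m:
        sign, lo, _hi, mid, mult = m.groups()
        ab = Abnormality(
            kind="marker",
            marker_id=mid or None,
            multiplicity=int(mult) if mult else (int(lo) if lo else 1),
            raw_text=raw,
            supernumerary=(sign == "+"),
        )
        if sign == "-":
            return Removal(target=ab, multiplicity=ab.multiplicity, raw_text=raw)
        return ab

    if re.fullmatch(r"\+?dmin", token):
        return Abnormality(kind="dmin", raw_text=raw, supernumerary=token.startswith("+"))
    if re.fullmatch(r"[+-]?r\d*", token):
        if token.startswith("-"):
            return Removal(target=Abnormality(kind="ring", raw_text=raw), raw_text=raw)
        return Abnormality(kind="ring", raw_text=raw, supernumerary=token.startswith("+"))
    if token == "inc":
        return None

    # general structural token
    sign = ""
    body = token
    if body and body[0] in "+-":
        sign, body = body[0], body[1:]

    mult = 1
    m = re.search(r"x(\d+)$", body)
    if m:
        mult = int(m.group(1))
        body = body[: m.start()]
    constitutional = False
    if body.endswith("c") and body.rfind(")") == len(body) - 2:
        constitutional = True
        body = body[:-1]

    segments = []  # (word, [groups])
    pos = 0
    while pos < len(body):
        m = re.match(r"(psu\s+dic|[a-z]+)", body[pos:])
        if not m:
            raise ParseError(f"cannot parse abnormality token {raw!r}")
        word = re.sub(r"\s+", " ", m.group(1))
        pos += m.end()
        groups, pos = _read_groups(body, pos)
        segments.append((word, groups))
    if not segments:
        raise ParseError(f"cannot parse abnormality token {raw!r}")

    def build(word: str, groups: list[str]) -> Abnormality:
        if word not in STRUCTURAL_WORDS:
            raise ParseError(f"unknown abnormality token {raw!r} (head {word!r})")
        kind = STRUCTURAL_WORDS[word]
        ab = Abnormality(kind=kind, raw_text=raw, supernumerary=(sign == "+"))
        if _is_opaque(groups):
            if kind not in ("derivative", "ider", "psu_dic", "dic"):
                raise UnsupportedDialectError(
                    f"long-form (segment) ISCN notation is not supported: {raw!r}"
                )
            ab.opaque = True
            if groups:
                ab.chromosomes = [
                    c for c in re.split(r"[;:]", groups[0]) if re.fullmatch(r"\d+|X|Y", c)
                ]
            warn(f"opaque segment-notation derivative retained without band content: {raw!r}")
            return ab
        if groups:
            ab.chromosomes = [c.strip() for c in re.split(r"[;:]", groups[0])]
        if len(groups) > 1:
            ab.breakpoints = _parse_bands_group(groups[1])
        return ab

    head_word, head_groups = segments[0]
    if STRUCTURAL_WORDS.get(head_word) in ("derivative", "ider") and (
        len(segments) > 1 or _is_opaque(head_groups) or len(head_groups) >= 1
    ):
        ab = build(head_word, head_groups[:1] if len(segments) > 1 else head_groups)
        if len(segments) > 1 and _is_opaque([g for _, gs in segments for g in gs]):
            ab.opaque = True
            warn(f"opaque segment-notation derivative retained without band content: {raw!r}")
        elif len(segments) > 1:
            for word, groups in segments[1:]:
                emb = build(word, groups)
                emb.raw_text = word + "".join(f"({g})" for g in groups)
                ab.embedded.append(emb)
    else:
        if len(segments) > 1:
            raise ParseError(f"unexpected compound abnormality token {raw!r}")
        ab = build(head_word, head_groups)

    ab.multiplicity = mult
    ab.constitutional = constitutional

    if sign == "-":
        return Removal(target=ab, multiplicity=mult, raw_text=raw)
    return ab


def _parse_clone(segment: str, record: KaryotypeRecord, is_donor: bool) -> Clone:
    m = _BRACKET_RE.search(segment)
    if not m:
        raise ParseError(f"clone missing cell-count bracket: {segment!r}", record.case_id)
    composite = m.group(1) == "cp"
    cell_count = int(m.group(2))
    head = segment[: m.start()]

    fields = _split_top(head, ",")
    if not fields or not fields[0]:
        raise ParseError(f"clone missing chromosome count: {segment!r}", record.case_id)

    cm = _COUNT_RE.match(fields[0])
    if not cm:
        raise ParseError(f"cannot parse chromosome count {fields[0]!r}", record.case_id)
    count_min = int(cm.group(1))
    count_max = int(cm.group(2)) if cm.group(2) else count_min
    ploidy_tag = int(cm.group(3)) if cm.group(3) else None
    rest = cm.group(4)
    tokens = fields[1:]
    if rest:  # e.g. "82~88<4n>XXXX" (missing comma in the source table)
        tokens = [rest] + tokens

    clone = Clone(
        count_min=count_min,
        count_max=count_max,
        ploidy_tag=ploidy_tag,
        cell_count=cell_count,
        composite=composite,
        is_donor=is_donor,
    )

    i = 0
    if i < len(tokens):
        sm = _SEX_RE.match(tokens[i])
        if sm:
            clone.sex_designation = sm.group(1)
            if sm.group(2):
                clone.ploidy_tag = int(sm.group(2))
            i += 1
    if i < len(tokens):
        lm = _LINEAGE_RE.match(tokens[i])
        if lm:
            clone.lineage_ref = lm.group(1)
            clone.doubling = int(lm.group(2)) if lm.group(2) else 1
            i += 1
            # "sl,x2" writes the doubling as its own token
            if i < len(tokens) and re.fullmatch(r"x(\d+)", tokens[i]):
                clone.doubling = int(tokens[i][1:])
                i += 1

    for tok in tokens[i:]:
        tok = tok.strip()
        if not tok:
            continue
        if tok == "inc":
            clone.incomplete = True
            continue
        parsed = parse_abnormality_token(tok, record)
        if parsed is None:
            continue
        if isinstance(parsed, Removal):
            clone.removals.append(parsed)
        else:
            clone.abnormalities.append(parsed)
    return clone


def parse_karyotype(case_id: str, text: str) -> KaryotypeRecord:
    """Parse one short-form ISCN karyotype string into a KaryotypeRecord."""
    record = KaryotypeRecord(case_id=case_id, clones=[])
    text = text.strip()

    m = re.search(r"\.\s*ish\b", text)
    if m:
        text = text[: m.start()]
        record.ish_stripped = True

    segments = _split_top(text, "/")
    # an annotation like "nonclonal w/clonal abnormalities[3]" contains a "/";
    # re-join any segment left without its cell-count bracket
    merged: list[str] = []
    for seg in segments:
        if merged and merged[-1] != "" and not _BRACKET_RE.search(merged[-1]):
            merged[-1] = merged[-1] + "/" + seg
        else:
            merged.append(seg)
    segments = merged
    donor = False
    for seg in segments:
        seg = seg.strip()
        if seg == "":
            donor = True  # "//" chimerism boundary: what follows is the donor
            continue
        if _NONCLONAL_RE.match(seg) or _PLOIDY_ENTRY_RE.match(seg):
            record.nonclonal_entries_skipped += 1
            continue
        record.clones.append(_parse_clone(seg, record, donor))
    if not record.clones:
        raise ParseError("karyotype contains no clones", case_id)
    return record


# ---------------------------------------------------------------------------
# lineage resolution

def _sex_counts(designation: str) -> dict:
    return {"X": designation.count("X"), "Y": designation.count("Y")}


def _match_removal(effective: dict, removal: Removal) -> tuple | None:
    """Find the inherited-multiset key a removal refers to.

    A removal may omit band lists ("-del(20)", "-der(16)t(1;16)"); matching
    requires kind + chromosomes (+ marker id), bands only when given.
    """
    t = removal.target
    for key, (ab, mult) in effective.items():
        if mult <= 0:
            continue
        if ab.kind != t.kind or ab.chromosomes != t.chromosomes:
            continue
        if ab.marker_id != t.marker_id:
            continue
        if t.breakpoints and ab.breakpoints != t.breakpoints:
            continue
        if t.embedded:
            if len(ab.embedded) != len(t.embedded):
                continue
            ok = True
            for ea, et in zip(ab.embedded, t.embedded):
                if ea.kind != et.kind or ea.chromosomes != et.chromosomes:
                    ok = False
                elif et.breakpoints and ea.breakpoints != et.breakpoints:
                    ok = False
            if not ok:
                continue
        return key
    return None


def _nearest_baseline(midpoint: float, record: KaryotypeRecord) -> int:
    d2, d4 = abs(midpoint - 46), abs(midpoint - 92)
    if d2 == d4:
        record.warn(f"ambiguous ploidy baseline at count midpoint {midpoint}; using 2")
        return 2
    return 2 if d2 < d4 else 4


def resolve_lineage(record: KaryotypeRecord) -> list[ResolvedClone]:
    """Expand sl/sdl/idem references into effective abnormality multisets."""
    resolved: list[ResolvedClone] = []
    abnormal_indices = [i for i, c in enumerate(record.clones) if not c.is_normal and not c.is_donor]
    stem_idx = abnormal_indices[0] if abnormal_indices else None
    sideline_order = abnormal_indices[1:]  # sdl1, sdl2, ... in listing order

    for idx, clone in enumerate(record.clones):
        effective: dict = {}
        shown_sex = _sex_counts(clone.sex_designation)
        baseline_hint: int | None = None

        if clone.lineage_ref is not None:
            if clone.lineage_ref in ("sl", "idem"):
                ref_idx = stem_idx
            else:
                k = int(clone.lineage_ref[3:])
                if k < 1 or k > len(sideline_order):
                    raise LineageError(
                        f"reference {clone.lineage_ref!r} has no matching sideline",
                        record.case_id,
                    )
                ref_idx = sideline_order[k - 1]
            if ref_idx is None or ref_idx >= idx:
                raise LineageError(
                    f"lineage reference {clone.lineage_ref!r} does not point to an earlier clone",
                    record.case_id,
                )
            parent = resolved[ref_idx]
            d = clone.doubling
            for key, (ab, mult) in parent.effective_abnormalities.items():
                effective[key] = (ab, mult * d)
            if not clone.sex_designation:
                shown_sex = {s: n * d for s, n in parent.shown_sex_counts.items()}
            if d >= 2:
                baseline_hint = parent.effective_ploidy_baseline * d

        for removal in clone.removals:
            key = _match_removal(effective, removal)
            if key is None:
                record.warn(
                    f"removal {removal.raw_text!r} does not match an inherited abnormality; ignored"
                )
                continue
            ab, mult = effective[key]
            effective[key] = (ab, max(0, mult - removal.multiplicity))

        for ab in clone.abnormalities:
            key = ab.key()
            if key in effective:
                prev, mult = effective[key]
                effective[key] = (prev, mult + ab.multiplicity)
            else:
                effective[key] = (ab, ab.multiplicity)

        if clone.ploidy_tag is not None:
            if clone.ploidy_tag in (2, 4):
                baseline = clone.ploidy_tag
            else:
                midpoint = (clone.count_min + clone.count_max) / 2
                baseline = _nearest_baseline(midpoint, record)
                record.warn(
                    f"ploidy tag {clone.ploidy_tag}n outside {{2n,4n}}; using nearest baseline {baseline}n"
                )
        elif baseline_hint is not None:
            baseline = baseline_hint
            if baseline not in (2, 4):
                midpoint = (clone.count_min + clone.count_max) / 2
                baseline = _nearest_baseline(midpoint, record)
                record.warn(
                    f"lineage doubling implies {baseline_hint}n baseline; using nearest {baseline}n"
                )
        else:
            baseline = _nearest_baseline((clone.count_min + clone.count_max) / 2, record)

        resolved.append(
            ResolvedClone(
                base=clone,
                effective_abnormalities=effective,
                effective_ploidy_baseline=baseline,
                shown_sex_counts=shown_sex,
            )
        )
    return resolved


# ---------------------------------------------------------------------------
# classification

def classify_ploidy(clone: Clone) -> str:
    """'tnt' | 'diploid_range' | 'other' from the 4n tag or count interval."""
    if clone.ploidy_tag == 4:
        return "tnt"
    if clone.count_min <= TNT_RANGE[1] and clone.count_max >= TNT_RANGE[0]:
        return "tnt"
    if DIPLOID_RANGE[0] <= clone.count_min and clone.count_max <= DIPLOID_RANGE[1]:
        return "diploid_range"
    return "other"


def count_unrelated_abnormalities(rc: ResolvedClone) -> int:
    """Number of acquired abnormality events relative to the ploidy baseline.

    Every event counts at its multiplicity (``add(7)(q36)x2`` and each written
    numerical token count separately -- the convention that reproduces the
    published per-case complexity labels).  Constitutional abnormalities are
    excluded.  Incomplete clones raise :class:`NotEvaluable`.
    """
    if rc.base.incomplete:
        raise NotEvaluable(rc.base)
    total = 0
    for ab, mult in rc.events():
        if ab.constitutional:
            continue
        total += mult
    return total


def classify_complexity(record: KaryotypeRecord, resolved: list[ResolvedClone] | None = None) -> str:
    """'complex' (>=3 unrelated abnormalities in any clone) | 'non_complex' | 'not_evaluable'."""
    if resolved is None:
        resolved = resolve_lineage(record)
    any_incomplete = False
    best = 0
    for rc in resolved:
        if rc.base.is_donor or rc.base.is_normal:
            continue
        try:
            n = count_unrelated_abnormalities(rc)
        except NotEvaluable:
            any_incomplete = True
            continue
        best = max(best, n)
    if best >= 3:
        return "complex"
    if any_incomplete:
        return "not_evaluable"
    return "non_complex"


def detect_related_pseudodiploid(
    record: KaryotypeRecord, resolved: list[ResolvedClone] | None = None
) -> str:
    """'related' | 'unrelated' | 'no_pseudodiploid_clone'.

    A pseudodiploid clone (35-57 chromosomes, clonal acquired abnormalities)
    is *related* to the T/NT clone(s) when a T/NT clone is written as a
    lineage doubling of it, or shares at least one identical acquired
    abnormality with it.
    """
    if resolved is None:
        resolved = resolve_lineage(record)

    def acquired_keys(rc: ResolvedClone) -> set:
        return {
            key
            for key, (ab, mult) in rc.effective_abnormalities.items()
            if mult > 0 and not ab.constitutional
        }

    pseudodiploid = [
        (i, rc)
        for i, rc in enumerate(resolved)
        if not rc.base.is_donor
        and classify_ploidy(rc.base) == "diploid_range"
        and acquired_keys(rc)
    ]
    # T/NT-side clones: strict 4n/81-103 calls, plus clones carried on a
    # tetraploid baseline whose losses pushed the count below 81 (e.g. a
    # doubled stemline at 77~79 chromosomes)
    tnt = [
        (i, rc)
        for i, rc in enumerate(resolved)
        if not rc.base.is_donor
        and (
            classify_ploidy(rc.base) == "tnt"
            or (rc.effective_ploidy_baseline == 4 and rc.base.count_max > DIPLOID_RANGE[1])
        )
    ]

    if not pseudodiploid:
        return "no_pseudodiploid_clone"

    pseudo_ids = {i for i, _ in pseudodiploid}
    abnormal_indices = [i for i, c in enumerate(record.clones) if not c.is_normal and not c.is_donor]
    stem_idx = abnormal_indices[0] if abnormal_indices else None
    sideline_order = abnormal_indices[1:]

    for i, rc in tnt:
        clone = rc.base
        if clone.lineage_ref is not None and clone.doubling >= 2:
            if clone.lineage_ref in ("sl", "idem"):
                ref_idx = stem_idx
            else:
                ref_idx = sideline_order[int(clone.lineage_ref[3:]) - 1]
            if ref_idx in pseudo_ids:
                return "related"
        mine = acquired_keys(rc)
        for _, prc in pseudodiploid:
            if mine & acquired_keys(prc):
                return "related"
    return "unrelated"


# ---------------------------------------------------------------------------
# serialization back to ISCN text

def clone_to_text(clone: Clone) -> str:
    """Render a clone back to short-form ISCN (raw abnormality tokens preserved)."""
    count = str(clone.count_min)
    if clone.count_max != clone.count_min:
        count += f"~{clone.count_max}"
    if clone.ploidy_tag is not None:
        count += f"<{clone.ploidy_tag}n>"
    fields = [count]
    if clone.sex_designation:
        fields.append(clone.sex_designation)
    if clone.lineage_ref:
        fields.append(
            clone.lineage_ref + (f"x{clone.doubling}" if clone.doubling > 1 else "")
        )
    items: list[tuple[str, str]] = []
    for ab in clone.abnormalities:
        items.append(("a", ab.raw_text))
    for rem in clone.removals:
        items.append(("r", rem.raw_text))
    fields.extend(text for _, text in items)
    if clone.incomplete:
        fields.append("inc")
    bracket = f"[{'cp' if clone.composite else ''}{clone.cell_count}]"
    return ",".join(fields) + bracket


def record_to_text(record: KaryotypeRecord) -> str:
    parts = []
    donor_started = False
    for clone in record.clones:
        if clone.is_donor and not donor_started:
            parts.append("")  # renders "//"
            donor_started = True
        parts.append(clone_to_text(clone))
    return "/".join(parts)
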