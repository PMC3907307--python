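"""Breakpoint-junction analysis: split alignment, classification, and friends.

The analyzer reverses the simulator: given a junction amplicon and the
reference genome it recovers the junction class (disomy-inversion,
inversion-telomere, inversion-translocation), the two breakpoints, the
junction microhomology or inserted sequence, and the disomic spacer
length.  Alignment is exact-k-mer seeding into a numpy k-mer index over
both strands followed by maximal ungapped extension — amplicons are
error-free and reference divergence is substitution-only, which is why an
ungapped local aligner suffices.

Breakpoint coordinates follow the maximal-forward-shift convention (shared
bases belong to the forward/disomic side); the simulator records truth the
same way, so round-trip comparisons are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import PlantedRepeat, ReferenceGenome
from .sequence import TELOMERE_UNIT, _bases_pair, revcomp

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

UNRESOLVED = "unresolved"


# ---------------------------------------------------------------------------
# k-mer seed index

class SeedIndex:
    """Sorted-array index of all forward-strand k-mers of a genome.

    Minus-strand hits are found by querying the reverse complement of the
    seed, so one index serves both strands.  Seeds containing N are never
    indexed or queried.
    """

    def __init__(self, genome: ReferenceGenome, k: int = 20):
        if k > 31:
            raise ValueError("k must fit in 62 bits")
        self.k = k
        self.genome = genome
        self._codes: dict[str, np.ndarray] = {}
        self._order: dict[str, np.ndarray] = {}
        for name, seq in genome.chromosomes.items():
            codes = self._encode_all(seq)
            order = np.argsort(codes, kind="stable").astype(np.int64)
            self._codes[name] = codes[order]
            self._order[name] = order

    def _encode_all(self, seq: str) -> np.ndarray:
        arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        n = len(arr) - self.k + 1
        if n <= 0:
            return np.empty(0, dtype=np.uint64)
        codes = np.zeros(n, dtype=np.uint64)
        bad = np.zeros(n, dtype=bool)
        for j in range(self.k):
            window = arr[j:j + n]
            codes = codes * np.uint64(4) + np.minimum(window, 3).astype(np.uint64)
            bad |= window == 255
        # N-containing k-mers get a sentinel beyond the valid code range
        codes[bad] = np.uint64(1) << np.uint64(2 * self.k)
        return codes

    @staticmethod
    def _encode_one(kmer: str) -> int | None:
        code = 0
        for ch in kmer:
            v = _BASE_CODE[ord(ch)]
            if v == 255:
                return None
            code = code * 4 + int(v)
        return code

    def lookup(self, kmer: str, max_hits: int = 50) -> list[tuple[str, int, str]]:
        """All (chrom, position, strand) where the seed matches the genome.

        Returns [] for seeds with more than ``max_hits`` total hits
        (repetitive, e.g. telomere arrays) — such seeds are uninformative
        anchors.
        """
        hits: list[tuple[str, int, str]] = []
        for strand, query in (("+", kmer), ("-", revcomp(kmer))):
            code = self._encode_one(query)
            if code is None:
                continue
            code = np.uint64(code)
            for name, codes in self._codes.items():
                lo = int(np.searchsorted(codes, code, side="left"))
                hi = int(np.searchsorted(codes, code, side="right"))
                if hi - lo > max_hits:
                    return []
                for idx in self._order[name][lo:hi]:
                    hits.append((name, int(idx), strand))
                if len(hits) > max_hits:
                    return []
        return hits


# ---------------------------------------------------------------------------
# split alignment

@dataclass(frozen=True)
class LocalAlignment:
    """Maximal ungapped exact local alignment of an amplicon to the reference.

    ``qstart/qend`` index the amplicon; ``rstart/rend`` the reference
    (0-based half-open).  On the minus strand, amplicon position ``qstart``
    corresponds to reference position ``rend - 1``.
    """

    qstart: int
    qend: int
    chrom: str
    rstart: int
    rend: int
    strand: str

    @property
    def length(self) -> int:
        return self.qend - self.qstart

    def ref_at_query(self, q: int) -> int:
        """Reference breakpoint coordinate at query position ``q`` (half-open)."""
        if self.strand == "+":
            return self.rstart + (q - self.qstart)
        return self.rend - (q - self.qstart)


@dataclass
class SplitAlignment:
    query: str
    left: LocalAlignment | None
    right: LocalAlignment | None
    alignments: list[LocalAlignment] = field(default_factory=list)

    @property
    def resolved(self) -> bool:
        return self.left is not None and self.right is not None and self.left != self.right


def _extend(query: str, ref: str, qpos: int, rpos: int, strand: str,
            chrom: str, k: int) -> LocalAlignment:
    """Maximal ungapped extension of an exact seed in both directions."""
    n, m = len(query), len(ref)
    if strand == "+":
        ql, rl = qpos, rpos
        while ql > 0 and rl > 0 and query[ql - 1] == ref[rl - 1]:
            ql -= 1
            rl -= 1
        qr, rr = qpos + k, rpos + k
        while qr < n and rr < m and query[qr] == ref[rr]:
            qr += 1
            rr += 1
        return LocalAlignment(ql, qr, chrom, rl, rr, "+")
    # minus strand: query[qpos + i] == complement(ref[rpos + k - 1 - i])
    ql, rr = qpos, rpos + k
    while ql > 0 and rr < m and _bases_pair(query[ql - 1], ref[rr]):
        ql -= 1
        rr += 1
    qr, rl = qpos + k, rpos
    while qr < n and rl > 0 and _bases_pair(query[qr], ref[rl - 1]):
        qr += 1
        rl -= 1
    return LocalAlignment(ql, qr, chrom, rl, rr, "-")


def split_align(amplicon: str, index: SeedIndex, min_anchor: int | None = None,
                stride: int = 10) -> SplitAlignment:
    """Seed-and-extend split alignment of a junction amplicon.

    Seeds of length ``index.k`` are taken every ``stride`` bases (plus the
    two terminal seeds); each hit is extended to a maximal ungapped local
    alignment and deduplicated by diagonal.  The returned pair is the
    alignment reaching furthest left on the query and the one reaching
    furthest right; their query overlap is candidate microhomology and a
    query gap is a candidate insertion.
    """
    amplicon = amplicon.upper()
    k = index.k
    min_anchor = min_anchor or k
    if len(amplicon) < 2 * min_anchor:
        raise ValueError("amplicon shorter than twice the anchor length")
    offsets = sorted(set(range(0, len(amplicon) - k + 1, stride)) | {len(amplicon) - k})
    seen: set[tuple[str, str, int]] = set()
    alignments: list[LocalAlignment] = []
    for q in offsets:
        for chrom, rpos, strand in index.lookup(amplicon[q:q + k]):
            diag = rpos + q if strand == "-" else rpos - q
            key = (chrom, strand, diag)
            if key in seen:
                continue
            seen.add(key)
            aln = _extend(amplicon, index.genome[chrom], q, rpos, strand, chrom, k)
            if aln.length >= min_anchor:
                alignments.append(aln)
    if not alignments:
        return SplitAlignment(amplicon, None, None, [])
    left = min(alignments, key=lambda a: (a.qstart, -a.length, a.chrom, a.rstart))
    right = min(alignments, key=lambda a: (-a.qend, -a.length, a.chrom, a.rstart))
    if left == right:
        return SplitAlignment(amplicon, left, None, alignments)
    return SplitAlignment(amplicon, left, right, alignments)


# ---------------------------------------------------------------------------
# junction calling

@dataclass
class JunctionCall:
    junction_type: str
    e: int | None = None               # forward-side breakpoint
    d: int | None = None               # reverse-side breakpoint
    chrom_forward: str | None = None
    chrom_reverse: str | None = None
    spacer_size: int | None = None
    mh_len: int = 0
    insertion: str | None = None
    insertion_origin: str | None = None
    hybrid_repeat: "HybridRepeatCall | None" = None
    diagnostic: str = ""


@dataclass
class HybridRepeatCall:
    family: str
    homology_length: int
    identity: float


def _telomere_side(query: str, boundary: int, side: str) -> tuple[int, int] | None:
    """Detect a telomeric query side; returns (pattern_start, units) or None.

    For ``side == "right"`` the tail ``query[boundary:]`` must be a run of
    >= 2 complete (TTAGGG) units (any phase); the pattern is then extended
    base-by-base leftward into the aligned portion, which is how shared
    junction bases with the telomere repeat are counted.
    """
    if side != "right":
        raise ValueError("only right-side telomere arrays are modeled")
    tail = query[boundary:]
    if len(tail) < 12:
        return None
    best = None
    for ph in range(6):
        rotated = TELOMERE_UNIT[ph:] + TELOMERE_UNIT[:ph]
        n_units = 0
        while tail.startswith(rotated * (n_units + 1)):
            n_units += 1
        if n_units >= 2 and (best is None or n_units > best[1]):
            best = (ph, n_units)
    if best is None:
        return None
    phase, units = best
    t0 = boundary
    m = 0
    while t0 > 0 and query[t0 - 1] == TELOMERE_UNIT[(phase - 1 - m) % 6]:
        t0 -= 1
        m += 1
    return t0, units


def call_junction(split: SplitAlignment, genome: ReferenceGenome) -> JunctionCall:
    """Classify a split alignment and measure microhomology/insertion/spacer.

    Classification, in order: (1) a telomeric right side (>= 2 complete
    repeat units beyond the aligned prefix) -> inversion-telomere; (2)
    sides on different chromosomes -> inversion-translocation; (3) one
    chromosome, opposite strands, reverse-side coordinate proximal to the
    forward-side coordinate -> disomy-inversion with spacer ``e - d``.
    Shared bases are assigned maximally to the forward (left/reference)
    side.
    """
    q = split.query
    left, right = split.left, split.right

    if left is None:
        return JunctionCall(UNRESOLVED, diagnostic="no anchored alignment")

    telo = None
    if right is None or right.qend < len(q):
        # no alignment reaches the query end: check for a new telomere array
        telo = _telomere_side(q, left.qend, "right")
    if telo is not None:
        t0, _units = telo
        mh = max(0, left.qend - t0)
        insertion = q[left.qend:t0] if t0 > left.qend else None
        return JunctionCall(
            "inversion_telomere",
            e=None,
            d=left.ref_at_query(left.qend),
            chrom_forward=left.chrom,
            chrom_reverse=None,
            mh_len=mh if insertion is None else 0,
            insertion=insertion,
        )

    if right is None:
        return JunctionCall(UNRESOLVED, diagnostic="single contiguous alignment")

    overlap = left.qend - right.qstart
    mh = max(0, overlap)
    gap = q[left.qend:right.qstart] if right.qstart > left.qend else None

    if left.chrom != right.chrom:
        q_join = left.qend if gap is None else right.qstart
        return JunctionCall(
            "inversion_translocation",
            e=right.ref_at_query(q_join),
            d=left.ref_at_query(left.qend),
            chrom_forward=right.chrom,
            chrom_reverse=left.chrom,
            mh_len=mh if gap is None else 0,
            insertion=gap,
        )

    if left.strand == right.strand:
        return JunctionCall(
            UNRESOLVED,
            diagnostic="sides on the same strand (no inversion geometry)")

    if left.strand == "+" and right.strand == "-":
        e = left.ref_at_query(left.qend)
        d = right.ref_at_query(left.qend if gap is None else right.qstart)
        if d >= e:
            return JunctionCall(
                UNRESOLVED, e=e, d=d,
                diagnostic="reverse-side coordinate distal to forward side")
        return JunctionCall(
            "disomy_inversion",
            e=e, d=d,
            chrom_forward=left.chrom,
            chrom_reverse=right.chrom,
            spacer_size=e - d,
            mh_len=mh if gap is None else 0,
            insertion=gap,
        )

    return JunctionCall(
        UNRESOLVED,
        diagnostic="minus-then-plus geometry (consistent with a ring fusion junction)")


# ---------------------------------------------------------------------------
# insertion origin

UNCLASSIFIABLE_SHORT = "unclassifiable_short"


def classify_insertion_origin(
    insertion: str,
    genome: ReferenceGenome,
    breakpoints: list[tuple[str, int]],
    *,
    window: int = 1000,
    min_identity: float = 0.9,
) -> tuple[str, tuple[str, int, str] | None]:
    """Locate the template of a junction insertion.

    Scans the ``window`` bp around each breakpoint for an ungapped match of
    the insertion at >= ``min_identity`` in either orientation
    (templated_direct / templated_inverted), then the circular
    mitochondrial donor, else untemplated.  Insertions shorter than 4 bp
    are reported unclassifiable.  Returns ``(kind, (chrom, start, strand)
    or None)``.
    """
    n = len(insertion)
    if n < 1:
        raise ValueError("empty insertion")
    if n < 4:
        return UNCLASSIFIABLE_SHORT, None
    max_mm = int(n * (1.0 - min_identity))

    def scan(hay: str, base: int, chrom: str):
        for oriented, strand in ((insertion, "+"), (revcomp(insertion), "-")):
            for start in range(len(hay) - n + 1):
                mm = 0
                for a, b in zip(oriented, hay[start:start + n]):
                    if a != b:
                        mm += 1
                        if mm > max_mm:
                            break
                else:
                    kind = "templated_direct" if strand == "+" else "templated_inverted"
                    return kind, (chrom, base + start, strand)
        return None

    for chrom, bp in breakpoints:
        seq = genome[chrom]
        lo = max(0, bp - window)
        hi = min(len(seq), bp + window)
        hit = scan(seq[lo:hi], lo, chrom)
        if hit:
            return hit
    if genome.mito_donor:
        doubled = genome.mito_donor + genome.mito_donor[:n - 1]
        hit = scan(doubled, 0, "mito_donor")
        if hit:
            return "mitochondrial", hit[1]
    return "untemplated", None


# ---------------------------------------------------------------------------
# hybrid repeats

def detect_hybrid_repeat(call: JunctionCall, genome: ReferenceGenome,
                         repeats: list[PlantedRepeat] | None = None,
                         *, min_length: int = 50,
                         min_identity: float = 0.7) -> HybridRepeatCall | None:
    """Repeat-mediated junction: both breakpoints inside one inverted pair.

    When the forward breakpoint ``e`` and reverse breakpoint ``d`` each
    fall inside a copy of the same annotated repeat family whose copies
    are inverted relative to each other, the two copies are aligned (one
    reverse-complemented) and the homology length and identity reported.
    """
    if call.junction_type != "disomy_inversion" or call.e is None or call.d is None:
        return None
    repeats = genome.repeats if repeats is None else repeats
    for rep in repeats:
        if rep.orientation != "inverted":
            continue
        iv1, iv2 = rep.copies
        if iv1.chrom != call.chrom_forward:
            continue
        inside = lambda iv, pos: iv.start <= pos <= iv.end
        if (inside(iv2, call.e) and inside(iv1, call.d)) or \
                (inside(iv1, call.e) and inside(iv2, call.d)):
            c1 = genome[iv1.chrom][iv1.start:iv1.end]
            c2 = genome[iv2.chrom][iv2.start:iv2.end]
            aligned = revcomp(c2)
            matches = sum(a == b for a, b in zip(c1, aligned))
            identity = matches / rep.length
            if rep.length >= min_length and identity >= min_identity:
                return HybridRepeatCall(rep.family, rep.length, identity)
    return None


# ---------------------------------------------------------------------------
# CGH segmentation

DUP_LOG2 = float(np.log2(3 / 2))
STATE_MEANS = {"deleted": -1.0, "disomic": 0.0, "duplicated": DUP_LOG2}
THRESH_DEL = -0.5            # midpoint of -1 and 0
THRESH_DUP = DUP_LOG2 / 2    # midpoint of 0 and log2(3/2), ~0.29


@dataclass
class CghSegment:
    start_index: int
    end_index: int          # half-open, probe indices
    state: str


@dataclass
class CghResult:
    profile: pd.DataFrame
    segments: list[CghSegment]
    spacer_estimate: int | None
    spacer_detected: bool


def segment_cgh(profile: pd.DataFrame, *, window: int = 5,
                min_segment: int = 3) -> CghResult:
    """Three-state segmentation of a log2-ratio profile.

    A centered ``window``-probe running mean is thresholded at the state
    midpoints; segments shorter than ``min_segment`` probes are merged into
    their left neighbor; each boundary is then refined within +/- ``window``
    probes to the split minimizing squared error against the two segment
    means.  The spacer estimate is the distance from the most distal
    duplicated probe to the most proximal deleted probe; the spacer counts
    as detected only if a disomic probe lies between them.
    """
    if len(profile) < 10:
        raise ValueError("need at least 10 probes")
    pos = profile["pos"].to_numpy()
    log2 = profile["log2"].to_numpy(dtype=float)
    n = len(log2)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, log2[0]), log2, np.full(pad, log2[-1])])
    smooth = np.convolve(padded, kernel, mode="valid")[:n]

    states = np.where(smooth < THRESH_DEL, "deleted",
                      np.where(smooth > THRESH_DUP, "duplicated", "disomic"))
    segments: list[CghSegment] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or states[i] != states[start]:
            segments.append(CghSegment(start, i, str(states[start])))
            start = i
    # merge runt segments leftward
    merged: list[CghSegment] = []
    for seg in segments:
        if merged and (seg.end_index - seg.start_index) < min_segment:
            merged[-1] = CghSegment(merged[-1].start_index, seg.end_index, merged[-1].state)
        elif merged and merged[-1].state == seg.state:
            merged[-1] = CghSegment(merged[-1].start_index, seg.end_index, merged[-1].state)
        else:
            merged.append(seg)
    if len(merged) == 1:
        seg = merged[0]
        est = None
        return CghResult(profile, merged, est, False)
    # Refine each boundary against the raw probes.  A boundary may slide far
    # enough to empty its segment entirely: smoothing ramps at duplicated ->
    # deleted steps fabricate short "disomic" runs whose raw probes belong to
    # the flanking states, and refinement is what removes them.
    for a, b in zip(merged[:-1], merged[1:]):
        mu_a, mu_b = STATE_MEANS[a.state], STATE_MEANS[b.state]
        cut0 = a.end_index
        lo = max(a.start_index, cut0 - window)
        hi = min(b.end_index, cut0 + window)
        best_cut, best_cost = cut0, np.inf
        for cut in range(lo, hi + 1):
            cost = (np.sum((log2[a.start_index:cut] - mu_a) ** 2)
                    + np.sum((log2[cut:b.end_index] - mu_b) ** 2))
            if cost < best_cost:
                best_cut, best_cost = cut, cost
        a.end_index = best_cut
        b.start_index = best_cut
    refined = [s for s in merged if s.end_index > s.start_index]
    merged = []
    for seg in refined:
        if merged and merged[-1].state == seg.state:
            merged[-1] = CghSegment(merged[-1].start_index, seg.end_index, seg.state)
        else:
            merged.append(seg)

    dup_idx = [i for s in merged if s.state == "duplicated"
               for i in (s.end_index - 1,)]
    del_idx = [i for s in merged if s.state == "deleted"
               for i in (s.start_index,)]
    if not dup_idx or not del_idx:
        return CghResult(profile, merged, None, False)
    dup_last = max(dup_idx)
    del_first = min(i for i in del_idx if i > dup_last) if any(i > dup_last for i in del_idx) else None
    if del_first is None:
        return CghResult(profile, merged, None, False)
    estimate = int(pos[del_first] - pos[dup_last])
    disomic_between = any(
        s.state == "disomic" and s.start_index > dup_last and s.end_index <= del_first + 1
        for s in merged)
    return CghResult(profile, merged, estimate, disomic_between)


# ---------------------------------------------------------------------------
# discordant read-pair clustering

@dataclass
class PairCluster:
    signature: str
    chrom1: str
    chrom2: str
    start: int
    end: int
    n_pairs: int


def _pair_signature(row, insert_mean: int, insert_sd: int) -> str | None:
    if row.chrom1 == "." or row.chrom2 == ".":
        return None
    if row.chrom1 != row.chrom2:
        return "interchromosomal"
    # order mates by reference coordinate
    first, second = ((row.ref_start1, row.ref_end1, row.strand1),
                     (row.ref_start2, row.ref_end2, row.strand2))
    if first[0] > second[0]:
        first, second = second, first
    span = second[1] - first[0]
    if first[2] == second[2]:
        return "inverted"
    if first[2] == "-" and second[2] == "+":
        return "everted"
    if span > insert_mean + 4 * insert_sd:
        return "span_too_long"
    if span < insert_mean - 4 * insert_sd:
        return "span_too_short"
    return None   # concordant


def cluster_discordant_pairs(pairs: pd.DataFrame, *, insert_mean: int = 400,
                             insert_sd: int = 40) -> list[PairCluster]:
    """Cluster discordant read pairs into candidate breakpoint intervals.

    A pair is discordant when its reference span falls outside
    ``insert_mean +/- 4 * insert_sd``, its orientation is not
    forward-reverse, its mates are everted, or they map to different
    chromosomes.  Discordant pairs sharing a signature (and chromosome
    pair) whose leftmost-mate positions lie within ``insert_mean`` of each
    other form one cluster; each cluster reports the interval spanned by
    its inner mate edges.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one pair")
    records = []
    for row in pairs.itertuples(index=False):
        sig = _pair_signature(row, insert_mean, insert_sd)
        if sig is None:
            continue
        c1, c2 = sorted((row.chrom1, row.chrom2))
        left = min(row.ref_start1, row.ref_start2)
        inner_lo = min(row.ref_end1, row.ref_end2)
        inner_hi = max(row.ref_start1, row.ref_start2)
        records.append((sig, c1, c2, left, inner_lo, inner_hi))
    clusters: list[PairCluster] = []
    records.sort()
    for sig, c1, c2, left, inner_lo, inner_hi in records:
        cur = clusters[-1] if clusters else None
        if (cur is not None and cur.signature == sig and cur.chrom1 == c1
                and cur.chrom2 == c2 and left - cur.end <= insert_mean):
            cur.start = min(cur.start, inner_lo)
            cur.end = max(cur.end, inner_hi)
            cur.n_pairs += 1
        else:
            clusters.append(PairCluster(sig, c1, c2, inner_lo, inner_hi, 1))
    return clusters


# ---------------------------------------------------------------------------
# microsatellite parent-of-origin inference

def infer_parental_origin(markers: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Parent-of-origin calls from microsatellite alleles and peak heights.

    Input columns: ``marker, region, child_alleles, child_doubled,
    mother_alleles, father_alleles`` where allele columns are
    comma-separated allele labels (empty string for an untested parent)
    and ``child_doubled`` names the allele whose peak height indicates two
    copies (duplicated-region markers only; empty otherwise).

    Rules — duplicated region: the doubled allele present in exactly one
    parent assigns the duplication to that parent.  Deleted region: a
    hemizygous child allele present in exactly one parent implies the
    deletion came from the *other* parent.  Identical parental genotypes
    are uninformative (U).  A child allele found in neither tested parent
    is a Mendelian inconsistency: flagged and excluded.  A missing parent
    still allows inference, flagged with a caveat.
    """
    def alleles(s):
        return set(str(s).split(",")) - {"", "nan"}

    calls = []
    for row in markers.itertuples(index=False):
        child = alleles(row.child_alleles)
        mother = alleles(row.mother_alleles)
        father = alleles(row.father_alleles)
        tested = {"mother": bool(mother), "father": bool(father)}
        caveat = not all(tested.values())
        origin, flag = "U", ""
        if tested["mother"] and tested["father"] and not child <= (mother | father):
            origin, flag = "excluded", "mendelian_inconsistency"
        elif row.region == "duplicated":
            doubled = str(row.child_doubled)
            in_m = doubled in mother
            in_f = doubled in father
            if tested["mother"] and tested["father"]:
                if in_f and not in_m:
                    origin = "paternal"
                elif in_m and not in_f:
                    origin = "maternal"
            elif tested["mother"]:
                origin = "paternal" if not in_m else "U"   # doubled allele absent in mother
            elif tested["father"]:
                origin = "maternal" if not in_f else "U"
        elif row.region == "deleted":
            if len(child) == 1:
                a = next(iter(child))
                in_m, in_f = a in mother, a in father
                if tested["mother"] and tested["father"]:
                    if in_m and not in_f:
                        origin = "paternal"    # maternal allele retained
                    elif in_f and not in_m:
                        origin = "maternal"
                elif tested["mother"]:
                    origin = "paternal" if in_m else "U"
                elif tested["father"]:
                    origin = "maternal" if in_f else "U"
        calls.append({"marker": row.marker, "region": row.region,
                      "origin": origin, "flag": flag,
                      "caveat": caveat and origin in ("paternal", "maternal")})
    per_marker = pd.DataFrame(calls)
    informative = per_marker[per_marker["origin"].isin(["paternal", "maternal"])]
    if len(informative) == 0:
        summary = {"origin": "U", "n_informative": 0, "caveat": False}
    else:
        votes = informative["origin"].value_counts()
        summary = {
            "origin": votes.idxmax(),
            "n_informative": int(len(informative)),
            "caveat": bool(informative["caveat"].any()),
        }
    return per_marker, summary
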