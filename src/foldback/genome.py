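"""Synthetic reference genomes with the structural features fold-back analysis assumes.

A :class:`ReferenceGenome` bundles chromosome sequences with the annotations
the simulator and analyzer need: telomere caps at both ends, a centromere
coordinate per chromosome (a coordinate only — it decides dicentric versus
acentric products, and carries no special sequence), planted diverged repeat
pairs in direct or inverted orientation (Alu/LINE-like, parameterized by
homology length and percent identity), and a circular mitochondrial-like
donor used only as an insertion source.

Divergence between repeat copies is substitution-only; this keeps all
junction arithmetic exact and matches how repeat homology is quantified
(percent identity over an alignment length).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .sequence import GenomeInterval, revcomp, telomere_array, write_fasta

BASES = "ACGT"
MITO_DONOR_LENGTH = 16_569  # circular donor, human-mtDNA-sized
DEFAULT_TELOMERE_UNITS = 500


class PlacementError(ValueError):
    """Repeat plan could not be realized (overlapping or out-of-range copies)."""


@dataclass(frozen=True)
class PlantedRepeat:
    """A planted pair of homologous repeat copies.

    ``identity`` is the realized fraction of identical positions when the
    two copies are aligned (the second copy reverse-complemented first when
    ``orientation == "inverted"``).
    """

    family: str
    copies: tuple[GenomeInterval, GenomeInterval]
    orientation: str  # "direct" | "inverted"
    identity: float
    length: int


@dataclass
class ReferenceGenome:
    chromosomes: dict[str, str]
    centromeres: dict[str, int]
    telomere_units: int = DEFAULT_TELOMERE_UNITS
    repeats: list[PlantedRepeat] = field(default_factory=list)
    mito_donor: str = ""

    def __getitem__(self, chrom: str) -> str:
        return self.chromosomes[chrom]

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def digest(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.chromosomes):
            h.update(name.encode())
            h.update(self.chromosomes[name].encode())
        return h.hexdigest()

    def with_edit(self, chrom: str, pos: int, bases: str) -> "ReferenceGenome":
        """Return a copy of the genome with ``bases`` written at ``pos``."""
        seq = self.chromosomes[chrom]
        if not 0 <= pos <= len(seq) - len(bases):
            raise IndexError("edit outside chromosome")
        new = dict(self.chromosomes)
        new[chrom] = seq[:pos] + bases + seq[pos + len(bases):]
        return replace(self, chromosomes=new)


def random_dna(rng: np.random.Generator, n: int,
               composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)) -> str:
    """iid random DNA with the given (A, C, G, T) composition."""
    if abs(sum(composition) - 1.0) > 1e-9:
        raise ValueError("composition must sum to 1")
    idx = rng.choice(4, size=n, p=composition)
    return idx.astype(np.uint8).choose(np.frombuffer(BASES.encode(), dtype=np.uint8)).tobytes().decode()


def _mutate_to_identity(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitute uniformly random positions so that the realized identity is exact."""
    n = len(seq)
    n_sub = round((1.0 - identity) * n)
    positions = rng.choice(n, size=n_sub, replace=False)
    arr = list(seq)
    for pos in positions:
        choices = [b for b in BASES if b != arr[pos]]
        arr[pos] = choices[rng.integers(3)]
    return "".join(arr)


def generate_reference(
    lengths: dict[str, int],
    *,
    seed: int,
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    telomere_units: int = DEFAULT_TELOMERE_UNITS,
    centromere_frac: float = 0.1,
    repeat_plan: list[dict] | None = None,
    with_mito: bool = True,
) -> ReferenceGenome:
    """Deterministically generate a reference genome.

    Every chromosome starts with a ``(CCCTAA)n`` cap (the p-terminal strand
    presentation of the telomere repeat) and ends with a ``(TTAGGG)n`` cap.
    The centromere sits at ``centromere_frac`` of each chromosome length
    (strictly inside it), mimicking a long q arm on which terminal events
    occur.  ``repeat_plan`` entries are dicts with keys ``chrom, family,
    start1, start2, length, identity, orientation``.
    """
    rng = np.random.default_rng(seed)
    cap_p = telomere_array(telomere_units)  # TTAGGG-strand units
    chroms: dict[str, str] = {}
    centromeres: dict[str, int] = {}
    cap_left = revcomp(cap_p)   # CCCTAA presentation at the p terminus
    for name, n in lengths.items():
        interior = n - 2 * len(cap_left)
        if interior <= 0:
            raise ValueError(f"chromosome {name} too short for telomere caps")
        chroms[name] = cap_left + random_dna(rng, interior, composition) + cap_p
        cen = int(n * centromere_frac)
        centromeres[name] = min(max(cen, len(cap_left) + 1), n - 2)
    genome = ReferenceGenome(chroms, centromeres, telomere_units)
    if with_mito:
        genome.mito_donor = generate_mito_donor(int(rng.integers(2**31)))
    for spec in repeat_plan or []:
        genome = plant_repeat_pair(
            genome, spec["chrom"], spec["family"],
            (spec["start1"], spec["start2"]), spec["length"],
            identity=spec.get("identity", 1.0),
            orientation=spec.get("orientation", "inverted"),
            rng=rng,
        )
    return genome


def plant_repeat_pair(
    genome: ReferenceGenome,
    chrom: str,
    family: str,
    starts: tuple[int, int],
    length: int,
    *,
    identity: float = 1.0,
    orientation: str = "inverted",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> ReferenceGenome:
    """Plant a pair of diverged repeat copies on one chromosome.

    The first copy keeps the existing reference bases; the second copy is a
    (reverse-complemented, for inverted orientation) clone of the first,
    mutated with point substitutions at uniformly random positions so the
    realized identity equals the request exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    if orientation not in ("direct", "inverted"):
        raise ValueError(f"unknown orientation {orientation!r}")
    s1, s2 = starts
    n = genome.length(chrom)
    iv1 = GenomeInterval(chrom, s1, s1 + length)
    iv2 = GenomeInterval(chrom, s2, s2 + length,
                         strand="-" if orientation == "inverted" else "+")
    if iv1.end > n or iv2.end > n:
        raise PlacementError("repeat copy extends past chromosome end")
    if max(iv1.start, iv2.start) < min(iv1.end, iv2.end):
        raise PlacementError("repeat copies overlap")
    copy1 = genome[chrom][s1:s1 + length]
    template = revcomp(copy1) if orientation == "inverted" else copy1
    copy2 = _mutate_to_identity(rng, template, identity) if identity < 1.0 else template
    genome = genome.with_edit(chrom, s2, copy2)
    genome.repeats.append(PlantedRepeat(family, (iv1, iv2), orientation, identity, length))
    return genome


# kept under the name the rest of the package uses for the inverted case
def plant_inverted_repeat_pair(genome, chrom, family, starts, length, **kw):
    kw.setdefault("orientation", "inverted")
    return plant_repeat_pair(genome, chrom, family, starts, length, **kw)


def generate_mito_donor(seed: int) -> str:
    """A circular ~16.6-kb donor sequence used only as an insertion source."""
    rng = np.random.default_rng(seed)
    return random_dna(rng, MITO_DONOR_LENGTH)


def mito_window(donor: str, start: int, length: int) -> str:
    """Extract a window from the circular donor (wraps around the origin)."""
    doubled = donor + donor
    start %= len(donor)
    return doubled[start:start + length]


# ---------------------------------------------------------------------------
# serialization

MITO_RECORD = "mito_donor"


def write_genome_fasta(genome: ReferenceGenome, handle) -> None:
    records = dict(genome.chromosomes)
    if genome.mito_donor:
        records[MITO_RECORD] = genome.mito_donor
    write_fasta(handle, records)


def load_genome(fasta_path, bed_path=None) -> ReferenceGenome:
    """Rebuild a ReferenceGenome from its FASTA and BED annotation files."""
    from .sequence import read_fasta

    records = read_fasta(str(fasta_path))
    mito = records.pop(MITO_RECORD, "")
    centromeres: dict[str, int] = {}
    telomere_units = DEFAULT_TELOMERE_UNITS
    repeats: list[PlantedRepeat] = []
    if bed_path is not None:
        with open(bed_path) as fh:
            rows = read_annotation_bed(fh)
        for chrom, start, end, name, _strand in rows:
            if name == "centromere":
                centromeres[chrom] = start
            elif name == "telomere_cap_p":
                telomere_units = (end - start) // 6
        repeats = repeats_from_bed(rows)
    for chrom in records:
        centromeres.setdefault(chrom, max(1, len(records[chrom]) // 10))
    return ReferenceGenome(records, centromeres, telomere_units, repeats, mito)


def write_annotation_bed(genome: ReferenceGenome, handle) -> None:
    """BED6 annotation: telomere caps, centromeres, planted repeats."""
    cap = 6 * genome.telomere_units
    rows = []
    for name, seq in genome.chromosomes.items():
        rows.append((name, 0, cap, "telomere_cap_p", 0, "-"))
        rows.append((name, len(seq) - cap, len(seq), "telomere_cap_q", 0, "+"))
        cen = genome.centromeres[name]
        rows.append((name, cen, cen + 1, "centromere", 0, "+"))
    for i, rep in enumerate(genome.repeats):
        for j, iv in enumerate(rep.copies):
            label = f"{rep.family}:pair{i}:copy{j}:{rep.orientation}:{rep.identity:.2f}"
            rows.append((iv.chrom, iv.start, iv.end, label, 0, iv.strand))
    rows.sort(key=lambda r: (r[0], r[1]))
    for row in rows:
        handle.write("\t".join(map(str, row)) + "\n")


def read_annotation_bed(handle) -> list[tuple[str, int, int, str, str]]:
    """Parse the BED6 produced by :func:`write_annotation_bed`."""
    out = []
    for line in handle:
        if not line.strip():
            continue
        chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")
        out.append((chrom, int(start), int(end), name, strand))
    return out


def repeats_from_bed(rows) -> list[PlantedRepeat]:
    """Reconstruct PlantedRepeat annotations from parsed BED rows."""
    by_pair: dict[str, list] = {}
    for chrom, start, end, name, strand in rows:
        parts = name.split(":")
        if len(parts) != 5 or not parts[1].startswith("pair"):
            continue
        family, pair_id, copy_id, orientation, identity = parts
        by_pair.setdefault(pair_id, [None, None])
        idx = int(copy_id.removeprefix("copy"))
        by_pair[pair_id][idx] = (
            GenomeInterval(chrom, start, end, strand), family, orientation, float(identity))
    out = []
    for pair_id in sorted(by_pair, key=lambda p: int(p.removeprefix("pair"))):
        (iv1, family, orientation, identity), (iv2, *_rest) = by_pair[pair_id]
        out.append(PlantedRepeat(family, (iv1, iv2), orientation, identity, len(iv1)))
    return out
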