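"""Inverted-microhomology null model and cohort summary statistics.

The null asks how much inverted microhomology random "spacers" carry by
chance: draw N intervals near chromosome q-termini, count for each the
microhomology between its 3' end and the reverse complement of its 5' end
(exact match, :func:`foldback.sequence.inverted_mh_self`), and compare the
observed junctions against the simulated ones with a combinatorial
empirical p-value — the number of m-junction subsets drawable from the c
simulated junctions at or above the microhomology threshold, divided by
the number drawable from all N.

Note on operators: the null statistic uses the spacer's own 5' end,
whereas the junction-level operator pairs the spacer's 3' end with the
bases just proximal of the spacer; the one-base-window difference is
recorded in the result metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .genome import ReferenceGenome
from .sequence import GenomeInterval, inverted_mh_self

COHORT_RESOURCE = "cohort_junctions.tsv"


# ---------------------------------------------------------------------------
# spacer simulation

def draw_spacers(
    genome: ReferenceGenome,
    n: int,
    *,
    max_len: int = 70_466,
    max_dist_from_end: int = 5_500_000,
    min_len: int = 100,
    seed: int = 0,
) -> list[GenomeInterval]:
    """Random spacer intervals near q-termini.

    Lengths are uniform on ``[min_len, max_len)`` and the distal end is
    uniform within ``max_dist_from_end`` of the q terminus (excluding the
    telomere cap) of a uniformly chosen eligible chromosome; chromosomes
    shorter than ``max_dist_from_end`` are excluded.  Deterministic given
    the seed.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    if max_dist_from_end < max_len:
        raise ValueError("max_dist_from_end must be >= max_len")
    rng = np.random.default_rng(seed)
    cap = 6 * genome.telomere_units
    eligible = [c for c in sorted(genome.chromosomes)
                if genome.length(c) >= max_dist_from_end + cap]
    if not eligible:
        raise ValueError("no chromosome long enough for the requested draw window")
    out = []
    for _ in range(n):
        chrom = eligible[int(rng.integers(len(eligible)))]
        L = genome.length(chrom)
        length = int(rng.integers(min_len, max_len))
        end = int(rng.integers(L - max_dist_from_end, L - cap + 1))
        start = max(end - length, 0)
        out.append(GenomeInterval(chrom, start, end))
    return out


@dataclass
class MicrohomologyNull:
    n: int
    threshold: int
    draws: list[tuple[GenomeInterval, int]]
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def c(self) -> int:
        """Number of simulated spacers with microhomology >= threshold."""
        return sum(v for k, v in self.counts.items() if k >= self.threshold)

    def tail_fraction(self, k: int) -> float:
        return sum(v for kk, v in self.counts.items() if kk >= k) / self.n

    def to_json(self) -> dict:
        return {
            "n": self.n,
            "threshold": self.threshold,
            "counts": {str(k): v for k, v in sorted(self.counts.items())},
            "c": self.c,
            "statistic": "inverted_mh_self (spacer 3' end vs revcomp of its own "
                         "5' end; junction-level operator differs by a one-base "
                         "window at the proximal side)",
        }


def null_distribution(genome: ReferenceGenome, intervals: list[GenomeInterval],
                      *, threshold: int = 2) -> MicrohomologyNull:
    """Per-spacer inverted microhomology and its tabulated distribution."""
    draws = []
    counts: dict[int, int] = {}
    for iv in intervals:
        k = inverted_mh_self(genome[iv.chrom][iv.start:iv.end])
        draws.append((iv, k))
        counts[k] = counts.get(k, 0) + 1
    return MicrohomologyNull(len(intervals), threshold, draws, counts)


def empirical_p(c: int, n: int, m: int) -> float:
    """Combinatorial empirical p-value ``C(c, m) / C(n, m)``.

    The proportion of m-junction groups drawn from the n simulated
    junctions in which every member meets the microhomology threshold,
    given c qualifying simulations.  Computed as the telescoping product
    ``prod_{i<m} (c - i) / (n - i)`` for numerical stability; 0 when
    ``c < m``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= c <= n:
        raise ValueError("require 0 <= c <= n")
    if m > n:
        raise ValueError("cannot draw more junctions than were simulated")
    if c < m:
        return 0.0
    p = 1.0
    for i in range(m):
        p *= (c - i) / (n - i)
    return p


# ---------------------------------------------------------------------------
# cohort table

def load_cohort() -> pd.DataFrame:
    """The packaged cohort of sequenced inverted-duplication junctions.

    One row per subject: chromosome arm, CNV type, deletion/duplication/
    spacer sizes in bp, and indicator columns for which junction classes
    were sequenced (dis_inv, inv_tel, inv_tra).
    """
    with resources.files("foldback.data").joinpath(COHORT_RESOURCE).open() as fh:
        return pd.read_csv(fh, sep="\t")


def cohort_stats(table: pd.DataFrame) -> dict:
    """Summary statistics over the cohort table.

    Spacer statistics are computed over rows with a sequenced
    disomy-inversion junction; junction counts sum the three indicator
    columns.
    """
    if len(table) == 0:
        raise ValueError("empty cohort table")
    dis = table[table["dis_inv"] == 1]
    counts = {
        "dis_inv_junctions": int(table["dis_inv"].sum()),
        "inv_tel_junctions": int(table["inv_tel"].sum()),
        "inv_tra_junctions": int(table["inv_tra"].sum()),
    }
    counts["total_junctions"] = sum(counts.values())
    if len(dis) == 0:
        return {"spacer": {"available": False}, "junction_counts": counts,
                "n_subjects": int(len(table))}
    spacers = dis["spacer_bp"]
    per_chrom = table.groupby("chrom_arm")["dis_inv"].sum().astype(int).to_dict()
    return {
        "spacer": {
            "available": True,
            "n": int(len(spacers)),
            "median_bp": float(spacers.median()),
            "min_bp": int(spacers.min()),
            "max_bp": int(spacers.max()),
        },
        "junction_counts": counts,
        "dis_inv_by_chrom_arm": per_chrom,
        "n_subjects": int(len(table)),
    }


def null_report(null: MicrohomologyNull, m_observed: int, *, seed: int | None = None,
                config: dict | None = None) -> dict:
    """JSON-ready summary of a null run plus the enrichment p-value."""
    rec = null.to_json()
    rec["m_observed"] = m_observed
    rec["p_value"] = empirical_p(null.c, null.n, m_observed)
    if seed is not None:
        rec["seed"] = seed
    if config:
        rec["config"] = config
    return rec


def write_null_tsv(null: MicrohomologyNull, handle) -> None:
    handle.write("chrom\tstart\tend\tmh\n")
    for iv, k in null.draws:
        handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{k}\n")


def dumps_report(rec: dict) -> str:
    return json.dumps(rec, indent=1, sort_keys=True)
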