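"""Window-partitioned even-placement design of the final marker panel.

The genome is walked chromosome by chromosome in fixed-length windows
(22 kb by default).  Within a window holding three or more priority-1
candidates, the pair (N_i, N_j) minimising the positional variance

    SD² = [(S − x̄)² + (N_i − x̄)² + (N_j − x̄)² + (E − x̄)²] / 4

over the point set {window start S, window end E, chosen positions} is
retained; windows with one or two candidates keep them all.  After a
window that selected markers, the next window starts at the rightmost
selected position (probe-anchored advancement); after an empty window it
starts at the window end.  A second pass fills still-empty windows with
the best single priority-2 candidate (the SD² minimiser, i.e. nearest the
window midpoint), and a final pass fills remaining gaps from a background
SNP database, preferring assay-validated markers.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from itertools import combinations

from .datamodel_io import (
    CandidateSnp,
    DesignConfig,
    GenomeLayout,
    Panel,
    PanelEntry,
    PassLabel,
    Priority,
)

__all__ = [
    "WindowState",
    "Window",
    "WindowLedger",
    "sd2",
    "best_pair",
    "best_single",
    "priority1_pass",
    "priority2_pass",
    "background_pass",
    "design_panel",
]

logger = logging.getLogger(__name__)


class WindowState(enum.Enum):
    EMPTY = "EMPTY"
    FILLED_1 = "FILLED_1"  # holds priority-1 selections
    FILLED_2 = "FILLED_2"  # filled by a later (P2 or background) pass


@dataclass
class Window:
    """A design window [start, end) on one chromosome (1-based start)."""

    chrom: str
    start: int
    end: int
    index: int
    state: WindowState = WindowState.EMPTY
    selections: list[tuple[CandidateSnp, PassLabel]] = field(default_factory=list)

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def n_selected(self) -> int:
        return len(self.selections)


@dataclass
class WindowLedger:
    """Ordered windows for one chromosome with the selections per pass."""

    chrom: str
    windows: list[Window] = field(default_factory=list)

    def empty_windows(self) -> list[Window]:
        return [w for w in self.windows if w.state is WindowState.EMPTY]

    def selections(self) -> list[tuple[CandidateSnp, int, PassLabel]]:
        return [
            (snp, w.index, label)
            for w in self.windows
            for snp, label in w.selections
        ]


# ---------------------------------------------------------------------------
# The SD² placement criterion
# ---------------------------------------------------------------------------


def sd2(window_start: int, window_end: int, chosen: list[int]) -> float:
    """Positional variance of {start, end} ∪ chosen (divisor = point count).

    For a chosen pair the divisor is 4; for a single candidate, 3.
    """
    if not chosen:
        raise ValueError("chosen position list must not be empty")
    points = [window_start, window_end, *chosen]
    mean = sum(points) / len(points)
    return sum((p - mean) ** 2 for p in points) / len(points)


def best_pair(window: Window, candidates: list[int]) -> tuple[int, int]:
    """Exhaustive SD²-minimising pair among >= 3 in-window candidates.

    Ties broken by the lexicographically smallest sorted (pos_i, pos_j).
    """
    inside = sorted(p for p in candidates if window.contains(p))
    if len(inside) < 3:
        raise ValueError("best_pair requires at least 3 candidates in the window")
    best: tuple[float, tuple[int, int]] | None = None
    for pi, pj in combinations(inside, 2):
        key = (sd2(window.start, window.end, [pi, pj]), (pi, pj))
        if best is None or key < best:
            best = key
    return best[1]


def best_single(window: Window, candidates: list[int]) -> int:
    """SD²-minimising single candidate — the one nearest the window
    midpoint; ties broken by the lower position."""
    inside = sorted(p for p in candidates if window.contains(p))
    if not inside:
        raise ValueError("no candidate inside window")
    return min(inside, key=lambda p: (sd2(window.start, window.end, [p]), p))


# ---------------------------------------------------------------------------
# Pass 1: priority-1 placement with probe-anchored window advancement
# ---------------------------------------------------------------------------


def priority1_pass(
    candidates: list[CandidateSnp],
    chrom: str,
    chrom_length: int,
    config: DesignConfig,
) -> tuple[list[CandidateSnp], WindowLedger]:
    """Walk the chromosome placing priority-1 markers window by window.

    Per window: 0 candidates -> window left EMPTY; 1–2 -> all reserved;
    >= 3 -> the SD²-minimising pair.  Whitelisted indels are always
    force-selected and count toward occupancy.  After any selection the
    next window starts at the rightmost selected position; after an empty
    window, at the window end.  The terminal partial window is treated
    identically.
    """
    snps = sorted(
        (c for c in candidates if c.locus.chrom == chrom),
        key=lambda c: c.locus.pos,
    )
    by_pos = {c.locus.pos: c for c in snps}
    ledger = WindowLedger(chrom=chrom)
    selections: list[CandidateSnp] = []
    taken: set[int] = set()

    start = 1
    index = 0
    length = config.window_length
    while start <= chrom_length:
        end = min(start + length, chrom_length + 1)
        window = Window(chrom=chrom, start=start, end=end, index=index)
        inside = [c for c in snps if window.contains(c.locus.pos) and c.locus.pos not in taken]
        indels = [c for c in inside if c.is_indel]
        plain = [c for c in inside if not c.is_indel]

        picked: list[CandidateSnp] = list(indels)  # special-interest, always placed
        if len(plain) >= 3:
            pi, pj = best_pair(window, [c.locus.pos for c in plain])
            picked.extend([by_pos[pi], by_pos[pj]])
        else:
            picked.extend(plain)

        for c in sorted(picked, key=lambda c: c.locus.pos):
            window.selections.append((c, PassLabel.PRIORITY1))
            taken.add(c.locus.pos)
            selections.append(c)
        if window.selections:
            window.state = WindowState.FILLED_1
            next_start = max(c.locus.pos for c, _ in window.selections)
            if next_start <= start:  # sole pick sat exactly on the window start
                next_start = end
        else:
            next_start = end
        ledger.windows.append(window)
        index += 1
        start = next_start
    return selections, ledger


# ---------------------------------------------------------------------------
# Pass 2: priority-2 gap fill
# ---------------------------------------------------------------------------


def priority2_pass(
    ledger: WindowLedger, candidates: list[CandidateSnp]
) -> list[CandidateSnp]:
    """Fill each still-empty window with its best single priority-2 marker.

    Windows that reserved markers in pass 1 are skipped.  A candidate is
    used at most once even when overlapping windows both contain it.
    """
    snps = sorted(
        (c for c in candidates if c.locus.chrom == ledger.chrom),
        key=lambda c: c.locus.pos,
    )
    by_pos = {c.locus.pos: c for c in snps}
    taken: set[int] = set()
    out: list[CandidateSnp] = []
    for window in ledger.windows:
        if window.state is not WindowState.EMPTY:
            continue
        avail = [p for p in by_pos if window.contains(p) and p not in taken]
        if not avail:
            continue
        pos = best_single(window, avail)
        snp = by_pos[pos]
        window.selections.append((snp, PassLabel.PRIORITY2))
        window.state = WindowState.FILLED_2
        taken.add(pos)
        out.append(snp)
    return out


# ---------------------------------------------------------------------------
# Pass 3: background (database) gap fill
# ---------------------------------------------------------------------------


def background_pass(
    ledger: WindowLedger, candidates: list[CandidateSnp]
) -> list[CandidateSnp]:
    """Fill remaining empty windows from the background SNP database.

    Assay-validated markers take precedence; then proximity to the window
    midpoint; then the lower position.  Windows with no available marker
    stay EMPTY.
    """
    snps = sorted(
        (c for c in candidates if c.locus.chrom == ledger.chrom),
        key=lambda c: c.locus.pos,
    )
    taken: set[int] = set()
    out: list[CandidateSnp] = []
    for window in ledger.windows:
        if window.state is not WindowState.EMPTY:
            continue
        avail = [
            c for c in snps if window.contains(c.locus.pos) and c.locus.pos not in taken
        ]
        if not avail:
            continue
        snp = min(
            avail,
            key=lambda c: (
                not c.validated,
                abs(c.locus.pos - window.midpoint),
                c.locus.pos,
            ),
        )
        window.selections.append((snp, PassLabel.BACKGROUND))
        window.state = WindowState.FILLED_2
        taken.add(snp.locus.pos)
        out.append(snp)
    return out


# ---------------------------------------------------------------------------
# Full design
# ---------------------------------------------------------------------------


def design_panel(
    genome: GenomeLayout,
    candidates: list[CandidateSnp],
    config: DesignConfig | None = None,
) -> tuple[Panel, dict[str, WindowLedger]]:
    """Run the three placement passes on every chromosome.

    Returns the Panel (entries sorted by genome order then position, each
    carrying its window index and pass label) and the per-chromosome
    window ledgers.  Deterministic for fixed inputs and config.
    """
    config = config or DesignConfig()
    p1 = [c for c in candidates if c.priority is Priority.P1]
    p2 = [c for c in candidates if c.priority is Priority.P2]
    background = [c for c in candidates if c.priority is Priority.BACKGROUND]

    entries: list[PanelEntry] = []
    ledgers: dict[str, WindowLedger] = {}
    for chrom, length in genome.chromosomes:
        sel1, ledger = priority1_pass(p1, chrom, length, config)
        sel2 = priority2_pass(ledger, p2)
        sel3 = background_pass(ledger, background)
        logger.info(
            "chromosome %s: %d priority-1, %d priority-2, %d background, %d windows empty",
            chrom,
            len(sel1),
            len(sel2),
            len(sel3),
            len(ledger.empty_windows()),
        )
        for snp, window_index, label in ledger.selections():
            entries.append(PanelEntry(snp, window_index, label))
        ledgers[chrom] = ledger

    order = {name: i for i, name in enumerate(genome.names)}
    entries.sort(key=lambda e: (order[e.snp.locus.chrom], e.snp.locus.pos))
    return Panel(entries=entries, design_config=config, genome=genome), ledgers
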