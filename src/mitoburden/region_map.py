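"""Coordinate system for the human mitochondrial genome (rCRS, NC_012920.1).

Maps every 1-based position of the circular 16,569-bp reference to a locus
(e.g. ``MT-ND3``, ``MT-TA``, ``D-loop``) and to a macro region used for all
size-adjusted rates: the four mtDNA-encoded OxPhos complexes (I, III, IV, V),
``tRNA``, ``rRNA``, ``D-loop`` and the complement macro ``Other``.

``Other`` collects every position claimed by two or more loci (gene overlaps
such as MT-ATP8/MT-ATP6, or tRNAs encoded on opposite strands) and every
position claimed by none (intergenic spacers), so that the macro partition is
total and disjoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

GENOME_LENGTH = 16569

MACRO_REGIONS = (
    "ComplexI",
    "ComplexIII",
    "ComplexIV",
    "ComplexV",
    "tRNA",
    "rRNA",
    "D-loop",
    "Other",
)

#: macros whose loci encode OxPhos polypeptides (MutPred/APOGEE scoreable)
PROTEIN_MACROS = frozenset({"ComplexI", "ComplexIII", "ComplexIV", "ComplexV"})


class RegionMapError(ValueError):
    """Raised for invalid annotation tables or out-of-range positions."""


@dataclass(frozen=True)
class MtRegion:
    """One annotated locus on the circular rCRS.

    ``start``/``end`` are 1-based inclusive; ``start > end`` wraps the origin
    (the D-loop spans 16024..16569 plus 1..576).
    """

    name: str
    start: int
    end: int
    macro: str
    strand: str = "H"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= GENOME_LENGTH and 1 <= self.end <= GENOME_LENGTH):
            raise RegionMapError(
                f"region {self.name}: coordinates {self.start}-{self.end} "
                f"outside 1..{GENOME_LENGTH}"
            )
        if self.macro not in MACRO_REGIONS:
            raise RegionMapError(f"region {self.name}: unknown macro {self.macro!r}")

    @property
    def size_bp(self) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return (GENOME_LENGTH - self.start + 1) + self.end

    def positions(self) -> np.ndarray:
        """All rCRS positions covered, in circular order."""
        if self.start <= self.end:
            return np.arange(self.start, self.end + 1)
        return np.concatenate(
            [np.arange(self.start, GENOME_LENGTH + 1), np.arange(1, self.end + 1)]
        )


class RegionMap:
    """Total, disjoint macro partition of the rCRS built from locus rows."""

    genome_length = GENOME_LENGTH

    def __init__(self, regions: list[MtRegion], max_unannotated_run: int = 50):
        self.regions = list(regions)
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise RegionMapError("duplicate locus names in annotation")

        cover_count = np.zeros(GENOME_LENGTH + 1, dtype=np.int32)  # index 0 unused
        self._locus_masks: dict[str, np.ndarray] = {}
        for reg in self.regions:
            mask = np.zeros(GENOME_LENGTH + 1, dtype=bool)
            mask[reg.positions()] = True
            self._locus_masks[reg.name] = mask
            cover_count += mask

        # long runs of unannotated sequence indicate a broken table, not the
        # small intergenic spacers the rCRS genuinely contains
        uncovered = np.flatnonzero(cover_count[1:] == 0) + 1
        if uncovered.size:
            runs = np.split(uncovered, np.flatnonzero(np.diff(uncovered) > 1) + 1)
            bad = [r for r in runs if r.size > max_unannotated_run]
            if bad:
                spans = ", ".join(f"{r[0]}-{r[-1]}" for r in bad)
                raise RegionMapError(
                    f"annotation leaves {sum(r.size for r in bad)} positions "
                    f"unassigned in runs longer than {max_unannotated_run} bp "
                    f"({spans}); is a locus missing?"
                )

        macro = np.full(GENOME_LENGTH + 1, "Other", dtype=object)
        exclusive = np.full(GENOME_LENGTH + 1, "Other", dtype=object)
        single = cover_count == 1
        for reg in self.regions:
            sel = self._locus_masks[reg.name] & single
            macro[sel] = reg.macro
            exclusive[sel] = reg.name
        macro[0] = exclusive[0] = ""
        self._macro = macro
        self._exclusive_locus = exclusive
        self._cover_count = cover_count

    # -- lookups ---------------------------------------------------------

    def _check_pos(self, pos: int) -> None:
        if not 1 <= pos <= GENOME_LENGTH:
            raise RegionMapError(f"position {pos} outside 1..{GENOME_LENGTH}")

    def loci_at(self, pos: int) -> tuple[str, ...]:
        self._check_pos(pos)
        return tuple(n for n, m in self._locus_masks.items() if m[pos])

    def macro_at(self, pos: int) -> str:
        self._check_pos(pos)
        return self._macro[pos]

    def locate(self, pos: int) -> tuple[tuple[str, ...], str]:
        """Return ``(locus names, macro region)`` for one position.

        Positions inside a multi-locus overlap return every claiming locus
        and macro ``Other``; unannotated positions return ``((), "Other")``.
        """
        return self.loci_at(pos), self.macro_at(pos)

    def locus_assignment(self, pos: int) -> str:
        """Exclusive locus for rate bookkeeping: the single claiming locus,
        or ``"Other"`` for overlaps and unannotated positions."""
        self._check_pos(pos)
        return self._exclusive_locus[pos]

    def locus_vector(self, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=np.int64)
        if positions.size and not (
            (positions >= 1).all() and (positions <= GENOME_LENGTH).all()
        ):
            raise RegionMapError("positions outside 1..16569")
        return self._exclusive_locus[positions]

    def macro_vector(self, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=np.int64)
        if positions.size and not (
            (positions >= 1).all() and (positions <= GENOME_LENGTH).all()
        ):
            raise RegionMapError("positions outside 1..16569")
        return self._macro[positions]

    def region_size(self, name: str) -> int:
        """Size in bp of a locus (all positions it claims, overlaps included)
        or of a macro region (its exclusive partition share)."""
        if name in self._locus_masks:
            return int(self._locus_masks[name].sum())
        if name in MACRO_REGIONS:
            return int((self._macro[1:] == name).sum())
        raise RegionMapError(f"unknown region {name!r}")

    def positions_of(self, name: str, exclusive: bool = False) -> np.ndarray:
        """Positions of a locus or macro; ``exclusive`` restricts a locus to
        positions it claims alone (macro regions are always exclusive)."""
        if name in MACRO_REGIONS and name not in self._locus_masks:
            return np.flatnonzero(self._macro == name)
        if name not in self._locus_masks:
            raise RegionMapError(f"unknown region {name!r}")
        mask = self._locus_masks[name]
        if exclusive:
            mask = mask & (self._cover_count == 1)
        return np.flatnonzero(mask)

    @property
    def locus_names(self) -> list[str]:
        return [r.name for r in self.regions]

    def loci_of_macro(self, macro: str) -> list[str]:
        return [r.name for r in self.regions if r.macro == macro]

    def macro_sizes(self) -> dict[str, int]:
        return {m: self.region_size(m) for m in MACRO_REGIONS}


def load_region_map(path: str | Path | None = None, max_unannotated_run: int = 50) -> RegionMap:
    """Load a locus annotation table (tab-separated: locus, start, end, macro,
    strand; ``#`` comments allowed). ``path=None`` loads the bundled rCRS
    annotation."""
    if path is None:
        source = resources.files("mitoburden.data") / "rcrs_regions.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    required = {"locus", "start", "end", "macro"}
    missing = required - set(df.columns)
    if missing:
        raise RegionMapError(f"annotation table missing columns: {sorted(missing)}")
    regions = [
        MtRegion(
            name=str(row.locus),
            start=int(row.start),
            end=int(row.end),
            macro=str(row.macro),
            strand=str(getattr(row, "strand", "H")),
        )
        for row in df.itertuples(index=False)
    ]
    return RegionMap(regions, max_unannotated_run=max_unannotated_run)
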