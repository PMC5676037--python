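"""Tabular genome I/O and circular-coordinate arithmetic.

All coordinates are 0-based half-open internally.  BED input is consumed
as-is; annotation tables may be declared 1-based and are converted on read.
The chromosome is circular: distances are measured along the shorter arc
and intervals wrapping past the declared length are split on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .errors import ConfigurationError, ParseError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomeContext:
    """A circular chromosome with its two cartographic reference points.

    Parameters
    ----------
    chrom_name
        Sequence name used in BED output.
    length_bp
        Chromosome length L in base pairs (the *M. smegmatis* chromosome is
        roughly 7 Mbp).
    oric_pos
        Coordinate of the replication origin *oriC*.  Defaults to 0 so that
        the linear coordinate system starts at the origin.
    ter_pos
        Coordinate of the terminus region *ter*; defaults to L/2, i.e. the
        point diametrically opposite *oriC*.
    """

    chrom_name: str
    length_bp: int
    oric_pos: int = 0
    ter_pos: int | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValidationError(f"length_bp must be positive, got {self.length_bp}")
        if self.ter_pos is None:
            object.__setattr__(self, "ter_pos", self.length_bp // 2)
        for name in ("oric_pos", "ter_pos"):
            v = getattr(self, name)
            if not 0 <= v < self.length_bp:
                raise ValidationError(f"{name}={v} outside [0, {self.length_bp})")
        if self.oric_pos == self.ter_pos:
            raise ValidationError("oriC and ter must be distinct coordinates")


@dataclass(frozen=True)
class Peak:
    """One ChIP-seq enrichment interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    fold_enrichment: float | None = None
    replicate_id: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"peak {self.name or ''}({self.start}, {self.end}): start must be < end"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def midpoint(self, ctx: GenomeContext | None = None) -> float:
        m = (self.start + self.end) / 2.0
        return m % ctx.length_bp if ctx is not None else m


@dataclass(frozen=True)
class Feature:
    """A gene or operon interval with strand, 0-based half-open."""

    feature_id: str
    start: int
    end: int
    strand: str
    kind: str = "operon"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"feature {self.feature_id}({self.start}, {self.end}): start must be < end"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"feature {self.feature_id}: strand must be '+' or '-', got {self.strand!r}"
            )


def circular_distance(a: int, b: int, ctx: GenomeContext) -> int:
    """Shortest arc distance between two coordinates on the circular chromosome.

    Returns ``min(|a - b|, L - |a - b|)``; symmetric and never larger than L/2.
    """
    for name, v in (("a", a), ("b", b)):
        if not 0 <= v < ctx.length_bp:
            raise ValidationError(f"coordinate {name}={v} outside [0, {ctx.length_bp})")
    d = abs(int(a) - int(b))
    return min(d, ctx.length_bp - d)


def circular_distance_array(a, b, length_bp: int):
    """Vectorised shortest-arc distance; operands broadcast as numpy arrays."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    return np.minimum(d, length_bp - d)


def _split_wrapping(peak: Peak, ctx: GenomeContext) -> list[Peak]:
    # Intervals running past L wrap onto [0, end - L); keep downstream logic linear.
    if peak.end <= ctx.length_bp:
        if peak.start >= ctx.length_bp:
            raise ValidationError(f"peak start {peak.start} beyond chromosome end")
        return [peak]
    head = replace(peak, end=ctx.length_bp)
    tail = replace(peak, start=0, end=peak.end - ctx.length_bp)
    logger.info("peak %s wraps the origin; split into two sub-intervals", peak.name)
    return [head, tail]


def read_peaks(
    path: str | Path,
    ctx: GenomeContext | None = None,
    replicate_id: str = "",
    fold_column: int | None = None,
) -> list[Peak]:
    """Read a BED-like tab-separated peak file.

    Columns: chrom, start, end[, name[, score]].  The score column is
    interpreted as fold enrichment; ``fold_column`` (0-based index) overrides
    which column carries it, since peak callers differ on where they print
    the enrichment value.  Returns peaks sorted by start.
    """
    peaks: list[Peak] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            if len(cols) < 3:
                raise ParseError(f"{path.name}:{lineno}: expected >=3 columns, got {len(cols)}")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValidationError(
                    f"{path.name}:{lineno}: inverted interval ({start}, {end})"
                )
            name = cols[3] if len(cols) >= 4 else f"peak_{lineno}"
            fold: float | None = None
            fold_idx = fold_column
            if fold_idx is None:
                if len(cols) >= 5:
                    fold_idx = 4
                elif len(cols) == 4:
                    # BED4 is ambiguous: a numeric 4th column is taken as the score.
                    try:
                        float(cols[3])
                        fold_idx = 3
                        name = f"peak_{lineno}"
                    except ValueError:
                        fold_idx = None
            if fold_idx is not None:
                try:
                    fold = float(cols[fold_idx])
                except (ValueError, IndexError) as exc:
                    raise ParseError(
                        f"{path.name}:{lineno}: cannot read fold enrichment from column {fold_idx + 1}"
                    ) from exc
                if fold < 0:
                    raise ValidationError(f"{path.name}:{lineno}: negative fold enrichment")
            peak = Peak(cols[0], start, end, fold, replicate_id, name)
            if ctx is not None:
                peaks.extend(_split_wrapping(peak, ctx))
            else:
                peaks.append(peak)
    return sorted(peaks, key=lambda p: (p.start, p.end))


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED3+name+score; round-trips with :func:`read_peaks`."""
    with Path(path).open("w") as fh:
        for p in peaks:
            score = "" if p.fold_enrichment is None else f"\t{p.fold_enrichment:g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}{score}\n")


def read_features(path: str | Path, coordinate_base: int = 0) -> list[Feature]:
    """Read a TSV feature table (id, start, end, strand[, kind]).

    ``coordinate_base=1`` declares 1-based closed input coordinates, which
    are converted to the internal 0-based half-open convention.
    """
    if coordinate_base not in (0, 1):
        raise ConfigurationError(f"coordinate_base must be 0 or 1, got {coordinate_base}")
    feats: list[Feature] = []
    seen: set[str] = set()
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            if len(cols) < 4:
                raise ParseError(f"{path.name}:{lineno}: expected >=4 columns")
            fid, strand = cols[0], cols[3]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-integer coordinates") from exc
            if coordinate_base == 1:
                start -= 1  # 1-based closed -> 0-based half-open keeps end as-is
            kind = cols[4] if len(cols) >= 5 else "operon"
            if fid in seen:
                logger.warning("duplicate feature id %r at %s:%d; keeping both", fid, path.name, lineno)
            seen.add(fid)
            feats.append(Feature(fid, start, end, strand, kind))
    return sorted(feats, key=lambda f: (f.start, f.end))


def write_features(features: Iterable[Feature], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for f in features:
            fh.write(f"{f.feature_id}\t{f.start}\t{f.end}\t{f.strand}\t{f.kind}\n")


def load_genome_config(path: str | Path) -> GenomeContext:
    """Load a YAML genome config: chrom_name, length_bp, oric_pos, ter_pos."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    try:
        return GenomeContext(
            chrom_name=str(cfg["chrom_name"]),
            length_bp=int(cfg["length_bp"]),
            oric_pos=int(cfg.get("oric_pos", 0)),
            ter_pos=None if cfg.get("ter_pos") is None else int(cfg["ter_pos"]),
        )
    except KeyError as exc:
        raise ConfigurationError(f"genome config missing field {exc}") from exc
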