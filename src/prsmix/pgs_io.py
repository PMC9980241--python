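"""Reading, validation, harmonization, and writing of polygenic-score weight files.

Scoring files follow the PGS Catalog flat-file convention: ``#``-prefixed
metadata lines followed by a tab-separated body whose columns are drawn from
``{rsID, chr_name, chr_position, effect_allele, other_allele, effect_weight}``.
Harmonization re-expresses every published weight per copy of a target genotype
panel's *alternative* allele, so that downstream scoring is a plain
dosage-times-weight sum.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantKey",
    "ScoringFile",
    "HarmonizedScoring",
    "ScoringFormatError",
    "ScoringValidationError",
    "parse_scoring_file",
    "harmonize",
    "write_scoring_file",
    "read_panel_variants",
    "is_strand_ambiguous",
]

_VALID_BASES = frozenset("ACGT")


class ScoringFormatError(ValueError):
    """A scoring file violates the expected flat-file format."""


class ScoringValidationError(ValueError):
    """A scoring file parses but violates a content invariant."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """A bi-allelic variant keyed by chromosome, 1-based position, ref and alt allele."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", str(self.chrom))
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt allele identical at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _VALID_BASES:
                raise ValueError(f"non-ACGT allele {allele!r} at {self.chrom}:{self.pos}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """True for palindromic allele pairs (A/T or C/G) whose strand cannot be resolved."""
    pair = {a1.upper(), a2.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass
class ScoringFile:
    """One published score: per-variant effect alleles and per-allele weights.

    ``records`` columns: ``rsid`` (nullable), ``chrom`` (nullable), ``pos``
    (nullable Int64), ``effect_allele``, ``other_allele`` (nullable),
    ``weight`` (float).
    """

    score_id: str
    trait_label: str
    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class HarmonizedScoring:
    """A score expressed per copy of the target panel's alt allele.

    ``records`` columns: ``chrom``, ``pos``, ``ref``, ``alt``, ``weight``;
    every row corresponds to a variant present in the panel.
    """

    score_id: str
    records: pd.DataFrame
    n_flipped: int = 0
    n_dropped: int = 0
    trait_label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    @property
    def variant_keys(self) -> list[VariantKey]:
        return [
            VariantKey(r.chrom, int(r.pos), r.ref, r.alt)
            for r in self.records.itertuples(index=False)
        ]

    def weight_map(self) -> dict[VariantKey, float]:
        return dict(zip(self.variant_keys, self.records["weight"].to_numpy()))


_COLUMN_ALIASES: Mapping[str, str] = {
    "rsid": "rsid",
    "rsids": "rsid",
    "snp": "rsid",
    "variant_id": "rsid",
    "chr_name": "chrom",
    "chr": "chrom",
    "chromosome": "chrom",
    "chr_position": "pos",
    "pos": "pos",
    "position": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "reference_allele": "other_allele",
    "effect_weight": "weight",
    "weight": "weight",
}

_META_RE = re.compile(r"^#+\s*([A-Za-z0-9_.\- ]+?)\s*[=:]\s*(.*)$")


def parse_scoring_file(path: str | Path) -> ScoringFile:
    """Parse a PGS-Catalog-style scoring file.

    Metadata lines start with ``#`` (``#key=value``); the first non-metadata
    line is the tab-separated header. ``score_id`` and ``trait_label`` are
    taken from ``pgs_id``/``pgs_name`` and ``trait_reported`` metadata when
    present, falling back to the file stem.

    Raises
    ------
    ScoringFormatError
        If a mandatory column (effect allele or weight) is missing.
    ScoringValidationError
        If the file contains duplicate variant identifiers or non-finite
        weights.
    """
    path = Path(path)
    metadata: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                m = _META_RE.match(line)
                if m:
                    metadata[m.group(1).strip().lower()] = m.group(2).strip()
                continue
            if line.strip():
                body_lines.append(line)

    score_id = metadata.get("pgs_id") or metadata.get("pgs_name") or path.stem
    trait_label = metadata.get("trait_reported", metadata.get("trait", ""))

    if not body_lines:
        records = _empty_records()
        return ScoringFile(score_id, trait_label, records, metadata)

    header = [_COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower())
              for c in body_lines[0].split("\t")]
    for mandatory in ("effect_allele", "weight"):
        if mandatory not in header:
            raise ScoringFormatError(
                f"{path.name}: missing mandatory column {mandatory!r} "
                f"(found {body_lines[0].split(chr(9))})"
            )

    rows = [line.split("\t") for line in body_lines[1:]]
    df = pd.DataFrame(rows, columns=header)
    df = df.loc[:, ~df.columns.duplicated()]
    records = _empty_records()
    for col in records.columns:
        if col in df.columns:
            records[col] = df[col]
    records["weight"] = pd.to_numeric(records["weight"], errors="coerce")
    records["pos"] = pd.to_numeric(records["pos"], errors="coerce").astype("Int64")
    for col in ("effect_allele", "other_allele"):
        records[col] = records[col].str.upper()

    if records["weight"].isna().any() or not np.isfinite(records["weight"]).all():
        bad = records.index[~np.isfinite(records["weight"].fillna(np.nan))].tolist()
        raise ScoringValidationError(f"{path.name}: non-finite weight at body rows {bad}")

    dup_key = _variant_identifier(records)
    dups = dup_key[dup_key.duplicated()].unique().tolist()
    if dups:
        raise ScoringValidationError(
            f"{path.name}: {len(dups)} duplicate variant identifier(s): {dups}"
        )

    bad_allele = records["other_allele"].notna() & (
        records["effect_allele"] == records["other_allele"]
    )
    if bad_allele.any():
        raise ScoringValidationError(
            f"{path.name}: effect allele equals other allele on rows "
            f"{records.index[bad_allele].tolist()}"
        )

    return ScoringFile(score_id, trait_label, records.reset_index(drop=True), metadata)


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame({
        "rsid": pd.Series(dtype="object"),
        "chrom": pd.Series(dtype="object"),
        "pos": pd.Series(dtype="Int64"),
        "effect_allele": pd.Series(dtype="object"),
        "other_allele": pd.Series(dtype="object"),
        "weight": pd.Series(dtype="float64"),
    })


def _variant_identifier(records: pd.DataFrame) -> pd.Series:
    has_pos = records["chrom"].notna() & records["pos"].notna()
    ident = records["rsid"].astype("object").copy()
    positional = (
        records["chrom"].astype(str) + ":" + records["pos"].astype(str)
        + ":" + records["effect_allele"].fillna("") + ":" + records["other_allele"].fillna("")
    )
    ident[has_pos] = positional[has_pos]
    return ident.fillna("row" + pd.Series(records.index.astype(str), index=records.index))


def harmonize(
    scoring: ScoringFile,
    panel: Sequence[VariantKey],
    rsid_map: Mapping[str, VariantKey] | None = None,
    keep_ambiguous: bool = False,
) -> HarmonizedScoring:
    """Harmonize a scoring file's effect alleles to a panel's alt alleles.

    For each record: if the effect allele is the panel's alt allele the weight
    is kept; if it is the panel's ref allele the weight is negated (counted in
    ``n_flipped``). Records absent from the panel, with an allele pair that
    matches neither panel orientation, or strand-ambiguous (A/T, C/G — unless
    ``keep_ambiguous``) are excluded and counted in ``n_dropped``. rsID-only
    records are resolved through ``rsid_map`` when provided, else dropped.
    """
    by_pos: dict[tuple[str, int], list[VariantKey]] = {}
    for key in panel:
        by_pos.setdefault((key.chrom, key.pos), []).append(key)
    if any(len(v) != len(set(v)) for v in by_pos.values()):
        raise ValueError("panel variant keys are not unique")

    kept_rows: list[tuple[str, int, str, str, float]] = []
    n_flipped = 0
    n_dropped = 0

    for rec in scoring.records.itertuples(index=False):
        if pd.notna(rec.chrom) and pd.notna(rec.pos):
            candidates = by_pos.get((str(rec.chrom), int(rec.pos)), [])
        elif rsid_map is not None and pd.notna(rec.rsid) and rec.rsid in rsid_map:
            key = rsid_map[rec.rsid]
            candidates = [key] if key in by_pos.get((key.chrom, key.pos), []) else []
        else:
            n_dropped += 1
            continue

        ea = rec.effect_allele
        oa = rec.other_allele if pd.notna(rec.other_allele) else None
        if ea is None or pd.isna(ea):
            n_dropped += 1
            continue
        if oa is not None and is_strand_ambiguous(ea, oa) and not keep_ambiguous:
            n_dropped += 1
            continue

        match = None
        for key in candidates:
            panel_pair = {key.ref, key.alt}
            if oa is not None:
                if {ea, oa} == panel_pair:
                    match = key
                    break
            elif ea in panel_pair:
                match = key
                break
        if match is None:
            n_dropped += 1
            continue
        if oa is None and is_strand_ambiguous(match.ref, match.alt) and not keep_ambiguous:
            n_dropped += 1
            continue

        if ea == match.alt:
            kept_rows.append((match.chrom, match.pos, match.ref, match.alt, rec.weight))
        else:  # effect allele is the panel ref: re-sign per alt-allele copy
            kept_rows.append((match.chrom, match.pos, match.ref, match.alt, -rec.weight))
            n_flipped += 1

    records = pd.DataFrame(
        kept_rows, columns=["chrom", "pos", "ref", "alt", "weight"]
    ).astype({"pos": "int64", "weight": "float64"})
    return HarmonizedScoring(
        score_id=scoring.score_id,
        records=records,
        n_flipped=n_flipped,
        n_dropped=n_dropped,
        trait_label=scoring.trait_label,
    )


def write_scoring_file(effects, path: str | Path) -> Path:
    """Write combined per-allele effects as a PGS-Catalog-style scoring file.

    ``effects`` is an :class:`~prsmix.mixer.AdjustedEffects` (or any object
    with ``variants`` (VariantKey list), ``gamma`` (weights), ``score_id`` and
    ``trait_label``). Weights are written with full ``repr`` precision so that
    ``parse_scoring_file`` round-trips them bit-comparably.
    """
    if len(effects.variants) == 0:
        raise ValueError("refusing to write an empty scoring file")
    path = Path(path)
    score_id = getattr(effects, "score_id", "COMBINED")
    trait_label = getattr(effects, "trait_label", "")
    with open(path, "w") as fh:
        fh.write(f"#pgs_id={score_id}\n")
        if trait_label:
            fh.write(f"#trait_reported={trait_label}\n")
        fh.write("rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n")
        for key, gamma in zip(effects.variants, np.asarray(effects.gamma, dtype=float)):
            fh.write(
                f"{key}\t{key.chrom}\t{key.pos}\t{key.alt}\t{key.ref}\t{float(gamma)!r}\n"
            )
    return path


def read_panel_variants(path: str | Path) -> list[VariantKey]:
    """Read a panel variant-definition TSV with columns chrom, pos, ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        VariantKey(r.chrom, int(r.pos), r.ref, r.alt)
        for r in df.itertuples(index=False)
    ]
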