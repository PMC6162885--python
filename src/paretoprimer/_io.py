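"""Readers, writers and configuration handling.

Reference sets are multi-record FASTA; candidate primer pairs are a flat TSV
(probeBase-style exports map onto it directly); results are written as two
TSV files, the full archive and its Pareto front.  Configuration is a flat
YAML mapping whose keys mirror the efficiency and search dataclass fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from . import efficiency as _eff
from .matching import ReferenceSet, ScoreVector
from .optimize import ArchiveEntry, SearchConfig, UserInputError
from .seqcore import IUPAC_OPTIONS, PrimerSetPair

__all__ = [
    "CandidateRecord",
    "read_fasta",
    "read_candidates",
    "write_results",
    "read_archive",
    "load_config",
    "config_from_mapping",
]


@dataclass(frozen=True)
class CandidateRecord:
    """One initial (possibly degenerate) primer pair with optional metadata."""

    id: str
    forward: str
    reverse: str
    domain: str | None = None
    amplicon_length: int | None = None


def read_fasta(path: str | Path) -> ReferenceSet:
    """Read a reference set from FASTA (wrapped or unwrapped, mixed case,
    CRLF tolerated).  The record id is the first whitespace-delimited header
    token.  Duplicate ids, empty files and non-IUPAC letters are errors."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise UserInputError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        for i, ch in enumerate(seq):
            if ch not in IUPAC_OPTIONS:
                raise UserInputError(
                    f"record {rec.id!r}: invalid character {ch!r} at position {i + 1}"
                )
        records.append((rec.id, seq))
    if not records:
        raise UserInputError(f"no FASTA records found in {path}")
    return ReferenceSet.of(records)


_REQUIRED_COLUMNS = ("id", "forward", "reverse")


def read_candidates(path: str | Path) -> list[CandidateRecord]:
    """Read candidate primer pairs from a TSV with header.

    Mandatory columns: ``id``, ``forward``, ``reverse``.  Optional columns:
    ``domain`` and ``amplicon_length`` (blank cells mean absent)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise UserInputError(f"candidate file {path} lacks column {col!r}")
    out: list[CandidateRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rid = getattr(row, "id")
        fwd = getattr(row, "forward")
        rev = getattr(row, "reverse")
        if not isinstance(fwd, str) or not isinstance(rev, str):
            raise UserInputError(f"row {row_no} of {path}: missing primer sequence")
        domain = getattr(row, "domain", None)
        if not isinstance(domain, str) or not domain.strip():
            domain = None
        amplen_raw = getattr(row, "amplicon_length", None)
        amplen: int | None = None
        if isinstance(amplen_raw, str) and amplen_raw.strip():
            try:
                amplen = int(amplen_raw)
            except ValueError as exc:
                raise UserInputError(
                    f"row {row_no} of {path}: bad amplicon_length {amplen_raw!r}"
                ) from exc
            if amplen <= 0:
                raise UserInputError(
                    f"row {row_no} of {path}: amplicon_length must be positive"
                )
        for seq in (fwd, rev):
            for ch in seq.upper():
                if ch not in IUPAC_OPTIONS:
                    raise UserInputError(
                        f"row {row_no} of {path}: invalid base {ch!r} in {seq!r}"
                    )
        out.append(CandidateRecord(rid, fwd.upper(), rev.upper(), domain, amplen))
    if not out:
        raise UserInputError(f"candidate file {path} has no data rows")
    return out


_RESULT_COLUMNS = [
    "forward", "reverse", "E", "C_fraction", "C_count", "M",
    "provenance", "restart",
]


def _entry_sort_key(entry: ArchiveEntry):
    s = entry.score
    return (-s.e, -s.c_fraction, s.m, entry.pair.forward, entry.pair.reverse)


def _entries_frame(entries: Sequence[ArchiveEntry]) -> pd.DataFrame:
    rows = [
        {
            "forward": ",".join(e.pair.forward),
            "reverse": ",".join(e.pair.reverse),
            "E": repr(e.score.e),
            "C_fraction": repr(e.score.c_fraction),
            "C_count": e.score.c_count,
            "M": repr(e.score.m),
            "provenance": e.provenance,
            "restart": e.restart,
        }
        for e in sorted(entries, key=_entry_sort_key)
    ]
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def write_results(
    archive: Sequence[ArchiveEntry],
    front: Sequence[ArchiveEntry],
    prefix: str | Path,
) -> tuple[Path, Path]:
    """Write ``<prefix>.archive.tsv`` and ``<prefix>.front.tsv``.

    Rows are ordered by descending E, then descending C, then ascending M,
    then lexicographically by primers; scores are written with full float
    precision so a read-back round trip is exact."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    archive_path = prefix.with_name(prefix.name + ".archive.tsv")
    front_path = prefix.with_name(prefix.name + ".front.tsv")
    _entries_frame(archive).to_csv(archive_path, sep="\t", index=False)
    _entries_frame(front).to_csv(front_path, sep="\t", index=False)
    return archive_path, front_path


def read_archive(path: str | Path) -> list[ArchiveEntry]:
    """Read back a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        pair = PrimerSetPair.of(row.forward.split(","), row.reverse.split(","))
        score = ScoreVector(
            float(row.E), float(row.C_fraction), int(row.C_count), float(row.M)
        )
        out.append(ArchiveEntry(pair, score, row.provenance, int(row.restart)))
    return out


# --------------------------------------------------------------------------
# Configuration

_RAMP_KEYS = {
    "tm_ramp", "self_dimer_ramp", "cross_dimer_ramp",
    "tm_range_ramp", "amplicon_range_ramp",
}
_THERMO_KEYS = {"table", "monovalent_mM", "primer_nM"}


def config_from_mapping(
    mapping: dict, base: _eff.EfficiencyConfig = _eff.DEFAULT_CONFIG
) -> _eff.EfficiencyConfig:
    """Build an :class:`EfficiencyConfig` from a flat key/value mapping.

    Ramp endpoints use ``<name>_zero_at`` / ``<name>_one_at`` keys; thermo
    parameters their plain field names.  Unknown keys raise."""
    eff_fields = {f.name for f in dataclasses.fields(_eff.EfficiencyConfig)}
    eff_updates: dict = {}
    ramp_updates: dict[str, dict[str, float]] = {}
    thermo_updates: dict = {}
    for key, value in mapping.items():
        if key in _THERMO_KEYS:
            thermo_updates[key] = value
            continue
        for ramp in _RAMP_KEYS:
            if key in (f"{ramp}_zero_at", f"{ramp}_one_at"):
                ramp_updates.setdefault(ramp, {})[key[len(ramp) + 1:]] = float(value)
                break
        else:
            if key in eff_fields and key not in _RAMP_KEYS and key != "thermo":
                eff_updates[key] = value
            else:
                raise UserInputError(f"unknown configuration key {key!r}")
    for ramp, ends in ramp_updates.items():
        old: _eff.FuzzyRamp = getattr(base, ramp)
        eff_updates[ramp] = _eff.FuzzyRamp(
            ends.get("zero_at", old.zero_at), ends.get("one_at", old.one_at)
        )
    if thermo_updates:
        eff_updates["thermo"] = dataclasses.replace(base.thermo, **thermo_updates)
    return dataclasses.replace(base, **eff_updates)


def load_config(path: str | Path) -> _eff.EfficiencyConfig:
    """Load a flat YAML file of threshold/ramp overrides."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return _eff.DEFAULT_CONFIG
    if not isinstance(data, dict):
        raise UserInputError(f"configuration {path} must be a flat mapping")
    return config_from_mapping(data)
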