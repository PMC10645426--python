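"""Format readers and writers shared by all stages.

Tabular outputs are TSV with ``#``-prefixed provenance header lines (tool
version, seed, parameters) that pandas skips on read, so every file is both
self-describing and diff-able.  FASTQ goes through Biopython and is gzip
transparent by suffix.  BED is 0-based half-open; malformed lines are
reported with their line number.
"""

from __future__ import annotations

import gzip
import io as _io
import json
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .energy_model import BASES, EnergyPWM, EnergyTable, FitStats, LogoMatrix
from .library_design import SpecseqLibrary
from .read_processing import FractionCounts


class BedParseError(ValueError):
    """A BED line failed validation; the message names the line."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def provenance_lines(meta: dict | None = None) -> list[str]:
    lines = [f"# specseq version: {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def write_tsv(path, df: pd.DataFrame, meta: dict | None = None,
              index: bool = False) -> None:
    with open(path, "w") as fh:
        for line in provenance_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# -- FASTQ -----------------------------------------------------------------

def read_fastq(path) -> Iterator[str]:
    """Yield read sequences (uppercase strings) from a FASTQ(.gz) file."""
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fastq"):
            yield str(record.seq).upper()


def read_sequences(path) -> Iterator[str]:
    """Reads from FASTQ(.gz) or plain one-sequence-per-line text, by sniffing."""
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == "@":
        yield from read_fastq(path)
    else:
        with _open_text(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    yield line.upper()


def write_fastq(path, reads: Iterable[tuple[str, str]]) -> None:
    """Write (name, sequence) pairs as FASTQ with a constant quality string."""
    def records():
        for name, seq in reads:
            rec = SeqRecord(Seq(seq), id=name, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            yield rec

    with _open_text(path, "wt") as fh:
        SeqIO.write(records(), fh, "fastq")


# -- counts ----------------------------------------------------------------

def write_counts(path, fc: FractionCounts, meta: dict | None = None) -> None:
    meta = {"library": fc.library.name,
            "core_pattern": fc.library.core_pattern, **(meta or {})}
    write_tsv(path, fc.to_frame(), meta)


def read_counts(path, library: SpecseqLibrary) -> FractionCounts:
    df = read_tsv(path)
    counts = {
        str(r.variant): (float(r.n_bound), float(r.n_unbound))
        for r in df.itertuples()
    }
    return FractionCounts(library=library, counts=counts)


# -- energy tables and models ----------------------------------------------

def write_energy_table(path, et: EnergyTable, units: str = "kT",
                       meta: dict | None = None) -> None:
    meta = {
        "reference": et.reference_variant,
        "units": units,
        "pseudocount": et.pseudocount,
        "min_reads": et.min_reads,
        **(meta or {}),
    }
    write_tsv(path, et.to_frame(units=units), meta)


def read_energy_table(path, library: SpecseqLibrary) -> EnergyTable:
    meta = read_metadata(path)
    df = read_tsv(path)
    energies = {str(r.variant): float(r.ddG) for r in df.itertuples()}
    counts = {
        str(r.variant): (float(r.n_bound), float(r.n_unbound))
        for r in df.itertuples()
    }
    return EnergyTable(
        library=library,
        reference_variant=meta["reference"],
        energies=energies,
        pseudocount=float(meta.get("pseudocount", "nan")),
        min_reads=float(meta.get("min_reads", "nan")),
        counts=counts,
    )


def read_metadata(path) -> dict:
    """Parse ``# key: value`` provenance lines from a TSV header."""
    meta = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ": " in body:
                k, v = body.split(": ", 1)
                meta[k] = v
    return meta


def write_epwm(path, pwm: EnergyPWM, meta: dict | None = None) -> None:
    meta = {
        "reference": pwm.reference_variant,
        "units": "kT",
        "residual_sd": pwm.fit.residual_sd,
        "r_squared": pwm.fit.r_squared,
        "n_variants_fit": pwm.fit.n_variants_fit,
        "max_mismatch": pwm.max_mismatch,
        "core_pattern": pwm.library.core_pattern,
        **(meta or {}),
    }
    write_tsv(path, pwm.to_frame(), meta)


def read_epwm(path, library: SpecseqLibrary) -> EnergyPWM:
    meta = read_metadata(path)
    df = read_tsv(path)
    beta: dict[tuple[int, str], float] = {}
    for r in df.itertuples():
        pos = int(r.position) - 1
        for b in BASES:
            beta[(pos, b)] = float(getattr(r, b))
    return EnergyPWM(
        library=library,
        reference_variant=meta["reference"],
        beta=beta,
        fit=FitStats(
            r_squared=float(meta.get("r_squared", "nan")),
            residual_sd=float(meta.get("residual_sd", "nan")),
            n_variants_fit=int(meta.get("n_variants_fit", 0)),
        ),
        max_mismatch=int(meta.get("max_mismatch", 2)),
    )


def write_logo_matrix(path, lm: LogoMatrix, meta: dict | None = None) -> None:
    meta = {
        "reference": lm.reference_variant,
        "units": "kT",
        "normalization": "per-column mean-centered; display is negation",
        "fixed_positions": ",".join(
            f"{p + 1}={b}" for p, b in sorted(lm.fixed_positions.items())
        ),
        **(meta or {}),
    }
    write_tsv(path, lm.to_frame(), meta)


# -- BED -------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a >= 4 column BED (chrom, start, end, name), validating each line."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"line {lineno}: expected >= 4 fields")
            chrom, start, end, name = fields[:4]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinates {start!r}, {end!r}"
                ) from None
            if end_i <= start_i or start_i < 0:
                raise BedParseError(
                    f"line {lineno}: invalid interval [{start_i}, {end_i})"
                )
            rows.append((chrom, start_i, end_i, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(path, df: pd.DataFrame) -> None:
    df[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# -- differential tables and expression matrices ---------------------------

def read_differential(path) -> pd.DataFrame:
    from .targetome import validate_differential

    df = read_tsv(path).set_index("id")
    return validate_differential(df, str(path))


def write_differential(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    out = df.reset_index()
    out = out.rename(columns={out.columns[0]: "id"})
    write_tsv(path, out, meta)


def read_expression_matrix(path) -> pd.DataFrame:
    return read_tsv(path, index_col=0)


def write_expression_matrix(path, df: pd.DataFrame,
                            meta: dict | None = None) -> None:
    write_tsv(path, df, meta, index=True)


# -- JSON reports ----------------------------------------------------------

def write_json(path, obj: dict, meta: dict | None = None) -> None:
    payload = {"provenance": {"specseq_version": __version__, **(meta or {})},
               **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
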