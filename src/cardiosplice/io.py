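"""Readers and writers for variant, gene-metadata and control-count tables.

All tables are tab-delimited text with a header row. Column names can be
remapped through a *dialect* (a logical-field -> column-name mapping, loadable
from a plain key=value file), so both in-house exports and synthetic tables
load through the same reader. Missing cells stay missing (``None``); they are
never coerced to 0.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from .models import (
    ConfigError,
    ConsequenceAnnotation,
    ControlCounts,
    DataError,
    Disease,
    FunctionalOutcome,
    GeneMeta,
    HaploinsufficiencyScore,
    OutcomeKind,
    SequencingMode,
    SpliceScores,
    SUBPOPULATIONS,
    VariantObservation,
)

__all__ = [
    "DEFAULT_DIALECT",
    "read_dialect",
    "read_variant_table",
    "write_variant_table",
    "read_gene_meta",
    "write_gene_meta",
    "read_control_table",
    "write_control_table",
    "read_vcf",
    "write_report",
    "format_percent",
]

#: logical field -> default column header
DEFAULT_DIALECT: dict[str, str] = {
    "participant_id": "participant_id",
    "disease": "disease",
    "gene": "gene",
    "transcript": "transcript",
    "hgvs_c": "hgvs_c",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "consequence": "consequence",
    "af_overall": "af_overall",
    **{f"af_{p}": f"af_{p}" for p in SUBPOPULATIONS},
    "allele_count_controls": "ac_controls",
    "mes_ref": "mes_ref",
    "mes_alt": "mes_alt",
    "mes_delta": "mes_delta",
    "ada": "ada",
    "rf": "rf",
    "spliceai": "spliceai",
    "proband_count": "proband_count",
    "informative_meioses": "informative_meioses",
    "functional_outcome": "functional_outcome",
    "functional_length_nt": "functional_length_nt",
    "sequencing_mode": "sequencing_mode",
    "exon_boundary_distance": "exon_boundary_distance",
    "reference_build": "reference_build",
}

MANDATORY_FIELDS = ("participant_id", "disease", "gene", "transcript", "hgvs_c")


def read_dialect(path: str | Path) -> dict[str, str]:
    """Load a column-mapping dialect from a ``field = column`` text file.

    Lines starting with ``#`` and blank lines are ignored; unmapped fields
    keep their default column names.
    """
    dialect = dict(DEFAULT_DIALECT)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'field = column'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in DEFAULT_DIALECT:
            raise ConfigError(f"{path}:{lineno}: unknown field {key!r}")
        dialect[key] = value
    return dialect


def _cell(row: Mapping[str, Any], dialect: Mapping[str, str], field: str) -> str | None:
    col = dialect[field]
    value = row.get(col)
    if value is None:
        return None
    value = str(value).strip()
    if value == "" or value.upper() in ("NA", "NAN", "."):
        return None
    return value


def _float(raw: str | None, field: str, rownum: int) -> float | None:
    if raw is None:
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise DataError(f"row {rownum}: malformed numeric {field}={raw!r}") from exc


def _int(raw: str | None, field: str, rownum: int) -> int | None:
    if raw is None:
        return None
    try:
        value = float(raw)
    except ValueError:
        raise DataError(f"row {rownum}: malformed integer {field}={raw!r}") from None
    if value != int(value):
        raise DataError(f"row {rownum}: non-integer {field}={raw!r}")
    return int(value)


def read_variant_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[VariantObservation]:
    """Read a variant-observation table (one row per carrier x variant)."""
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    for field in MANDATORY_FIELDS:
        if dialect[field] not in df.columns:
            raise ConfigError(
                f"{path}: mandatory column {dialect[field]!r} (field {field}) missing"
            )

    records: list[VariantObservation] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        rownum = i + 2  # 1-based, counting the header
        cell = lambda f: _cell(row, dialect, f)  # noqa: E731
        try:
            outcome = None
            kind_raw = cell("functional_outcome")
            if kind_raw is not None:
                outcome = FunctionalOutcome(
                    kind=OutcomeKind(kind_raw),
                    affected_length_nt=_int(cell("functional_length_nt"),
                                            "functional_length_nt", rownum),
                )
            subpops = {}
            for p in SUBPOPULATIONS:
                af = _float(cell(f"af_{p}"), f"af_{p}", rownum)
                if af is not None:
                    subpops[p] = af
            consequence_raw = cell("consequence")
            mode_raw = cell("sequencing_mode")
            records.append(
                VariantObservation(
                    participant_id=cell("participant_id"),
                    disease=Disease(cell("disease")),
                    gene=cell("gene"),
                    transcript=cell("transcript"),
                    hgvs_c=cell("hgvs_c"),
                    chrom=cell("chrom"),
                    pos=_int(cell("pos"), "pos", rownum),
                    ref=cell("ref"),
                    alt=cell("alt"),
                    consequence=(
                        ConsequenceAnnotation(consequence_raw) if consequence_raw else None
                    ),
                    af_overall=_float(cell("af_overall"), "af_overall", rownum),
                    af_subpops=subpops,
                    allele_count_controls=_int(
                        cell("allele_count_controls"), "ac_controls", rownum
                    ),
                    scores=SpliceScores(
                        mes_ref=_float(cell("mes_ref"), "mes_ref", rownum),
                        mes_alt=_float(cell("mes_alt"), "mes_alt", rownum),
                        mes_delta=_float(cell("mes_delta"), "mes_delta", rownum),
                        ada=_float(cell("ada"), "ada", rownum),
                        rf=_float(cell("rf"), "rf", rownum),
                        spliceai=_float(cell("spliceai"), "spliceai", rownum),
                    ),
                    proband_count=_int(cell("proband_count"), "proband_count", rownum) or 0,
                    informative_meioses=_int(
                        cell("informative_meioses"), "informative_meioses", rownum
                    ) or 0,
                    functional_outcome=outcome,
                    sequencing_mode=(
                        SequencingMode(mode_raw) if mode_raw else SequencingMode.exome
                    ),
                    exon_boundary_distance=_int(
                        cell("exon_boundary_distance"), "exon_boundary_distance", rownum
                    ),
                    reference_build=cell("reference_build") or "GRCh38",
                )
            )
        except DataError:
            raise
        except (ValueError, KeyError) as exc:
            raise DataError(f"row {rownum}: {exc}") from exc
    return records


def _obs_to_row(obs: VariantObservation) -> dict[str, Any]:
    row: dict[str, Any] = {
        "participant_id": obs.participant_id,
        "disease": obs.disease.value,
        "gene": obs.gene,
        "transcript": obs.transcript,
        "hgvs_c": obs.hgvs_c,
        "chrom": obs.chrom,
        "pos": obs.pos,
        "ref": obs.ref,
        "alt": obs.alt,
        "consequence": obs.consequence.value if obs.consequence else None,
        "af_overall": obs.af_overall,
    }
    for p in SUBPOPULATIONS:
        row[f"af_{p}"] = obs.af_subpops.get(p)
    row.update(
        {
            "ac_controls": obs.allele_count_controls,
            "mes_ref": obs.scores.mes_ref,
            "mes_alt": obs.scores.mes_alt,
            "mes_delta": obs.scores.mes_delta,
            "ada": obs.scores.ada,
            "rf": obs.scores.rf,
            "spliceai": obs.scores.spliceai,
            "proband_count": obs.proband_count,
            "informative_meioses": obs.informative_meioses,
            "functional_outcome": (
                obs.functional_outcome.kind.value if obs.functional_outcome else None
            ),
            "functional_length_nt": (
                obs.functional_outcome.affected_length_nt if obs.functional_outcome else None
            ),
            "sequencing_mode": obs.sequencing_mode.value,
            "exon_boundary_distance": obs.exon_boundary_distance,
            "reference_build": obs.reference_build,
        }
    )
    return row


def write_variant_table(
    observations: Sequence[VariantObservation], path: str | Path
) -> None:
    """Write observations to TSV in the default dialect (lossless round-trip)."""
    columns = list(DEFAULT_DIALECT.values())
    df = pd.DataFrame([_obs_to_row(o) for o in observations], columns=columns)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_gene_meta(path: str | Path) -> dict[str, GeneMeta]:
    """Read a per-gene metadata table.

    Columns: gene, diseases (comma/semicolon-separated), lof_mechanism,
    haploinsufficiency, lof_oe, mean_sequenced_controls, is_ttn (optional).
    Duplicate gene symbols are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    required = {"gene", "diseases", "lof_mechanism", "haploinsufficiency",
                "mean_sequenced_controls"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns {sorted(missing)}")
    meta: dict[str, GeneMeta] = {}
    for i, row in enumerate(df.to_dict(orient="records")):
        rownum = i + 2
        gene = row["gene"].strip()
        if gene in meta:
            raise ConfigError(f"{path}: duplicate gene {gene!r} (row {rownum})")
        diseases_raw = row["diseases"].replace(";", ",")
        diseases = frozenset(
            Disease(tok.strip()) for tok in diseases_raw.split(",") if tok.strip()
        )
        hi_raw = row["haploinsufficiency"].strip()
        try:
            hi = HaploinsufficiencyScore(hi_raw)
        except ValueError:
            raise ConfigError(
                f"{path}: row {rownum}: haploinsufficiency {hi_raw!r} not in "
                "{3, 2, 1, not_curated}"
            ) from None
        oe_raw = row.get("lof_oe", "").strip()
        is_ttn_raw = str(row.get("is_ttn", "")).strip().lower()
        meta[gene] = GeneMeta(
            gene=gene,
            definitive_for=diseases,
            lof_mechanism=row["lof_mechanism"].strip().lower() in ("true", "1", "yes"),
            haploinsufficiency_score=hi,
            lof_oe=_float(oe_raw or None, "lof_oe", rownum),
            mean_sequenced_controls=float(row["mean_sequenced_controls"]),
            is_ttn=(is_ttn_raw in ("true", "1", "yes")) or gene == "TTN",
        )
    return meta


def write_gene_meta(meta: Mapping[str, GeneMeta], path: str | Path) -> None:
    rows = []
    for gene in sorted(meta):
        m = meta[gene]
        rows.append(
            {
                "gene": gene,
                "diseases": ",".join(sorted(d.value for d in m.definitive_for)),
                "lof_mechanism": str(m.lof_mechanism).lower(),
                "haploinsufficiency": m.haploinsufficiency_score.value,
                "lof_oe": m.lof_oe,
                "mean_sequenced_controls": m.mean_sequenced_controls,
                "is_ttn": str(m.is_ttn).lower(),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="")


def read_control_table(path: str | Path) -> dict[str, ControlCounts]:
    """Read the gnomAD-like control table: gene, qualifying_allele_count,
    mean_sequenced_individuals."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"gene", "qualifying_allele_count", "mean_sequenced_individuals"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns {sorted(missing)}")
    table: dict[str, ControlCounts] = {}
    for row in df.to_dict(orient="records"):
        gene = str(row["gene"]).strip()
        if gene in table:
            raise ConfigError(f"{path}: duplicate gene {gene!r}")
        table[gene] = ControlCounts(
            gene=gene,
            qualifying_allele_count=float(row["qualifying_allele_count"]),
            mean_sequenced_individuals=float(row["mean_sequenced_individuals"]),
        )
    return table


def write_control_table(table: Mapping[str, ControlCounts], path: str | Path) -> None:
    rows = [
        {
            "gene": g,
            "qualifying_allele_count": c.qualifying_allele_count,
            "mean_sequenced_individuals": c.mean_sequenced_individuals,
        }
        for g, c in sorted(table.items())
    ]
    # %.17g keeps the round-trip bit-exact for float denominators
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_vcf(
    path: str | Path,
    disease: Disease,
    spliceai_info: str = "SpliceAI",
    participant_id: str = "unknown",
) -> list[VariantObservation]:
    """Optional VCF ingestion: reads SpliceAI delta scores from an INFO field
    (``ALLELE|SYMBOL|DS_AG|DS_AL|DS_DG|DS_DL|...``) and emits the same
    observation records as the TSV reader. Requires pysam.
    """
    import pysam  # optional dependency

    def _info_or(rec, key, default):
        # pysam raises on keys absent from the header; treat as missing
        try:
            return rec.info[key]
        except (KeyError, ValueError):
            return default

    records: list[VariantObservation] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info.get(spliceai_info)
            if info is None:
                continue
            entries = info if isinstance(info, (tuple, list)) else [info]
            for entry in entries:
                fields = str(entry).split("|")
                if len(fields) < 6:
                    continue
                gene = fields[1]
                try:
                    deltas = [float(x) for x in fields[2:6] if x not in ("", ".")]
                except ValueError:
                    continue
                hgvs = _info_or(rec, "HGVSc", f"c.{rec.pos}N>N")
                records.append(
                    VariantObservation(
                        participant_id=participant_id,
                        disease=disease,
                        gene=gene,
                        transcript=str(_info_or(rec, "Transcript", "NA")),
                        hgvs_c=str(hgvs),
                        chrom=str(rec.chrom),
                        pos=int(rec.pos),
                        ref=str(rec.ref),
                        alt=str(rec.alts[0]) if rec.alts else None,
                        scores=SpliceScores(spliceai=max(deltas) if deltas else None),
                    )
                )
    return records


def format_percent(fraction: float, decimals: int = 1) -> str:
    """Render a fraction as a percentage, round-half-up (0.10305 -> '10.3')."""
    q = Decimal("1") if decimals == 0 else Decimal("0." + "0" * (decimals - 1) + "1")
    return str(Decimal(str(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


def _format_value(key: str, value: Any) -> Any:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        if key == "p" or key.startswith("p_") or key.endswith("_p"):
            return f"{value:.3e}"
        if key.endswith("_pct") or key.endswith("_percent"):
            return format_percent(value / 100.0) if value > 1 else format_percent(value)
        return f"{value:.6g}"
    return value


def _plain(value: Any) -> Any:
    if isinstance(value, enum.Enum):
        return value.value
    return value


def _as_records(results: Any) -> tuple[list[dict[str, Any]], list[str] | None]:
    """Normalise results to (records, columns); columns survive empty inputs
    when the container knows them (DataFrame)."""
    if isinstance(results, pd.DataFrame):
        return results.to_dict(orient="records"), list(results.columns)
    if isinstance(results, Mapping):
        return [dict(results)], list(results.keys())
    records = []
    for item in results:
        if dataclasses.is_dataclass(item):
            records.append({k: _plain(v) for k, v in dataclasses.asdict(item).items()})
        elif isinstance(item, Mapping):
            records.append({k: _plain(v) for k, v in item.items()})
        else:
            raise ConfigError(f"cannot serialise result item of type {type(item)}")
    return records, (list(records[0].keys()) if records else None)


def write_report(
    results: Any,
    path: str | Path,
    format: str = "tsv",
    columns: Sequence[str] | None = None,
) -> None:
    """Write pipeline output with deterministic column order and fixed float
    precision (percentages to 1 decimal, p-values in scientific notation)."""
    records, inferred = _as_records(results)
    columns = list(columns) if columns is not None else inferred
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(records, indent=2, default=str) + "\n")
        return
    if format != "tsv":
        raise ConfigError(f"unknown report format {format!r}")
    if columns is None:
        path.write_text("")
        return
    lines = ["\t".join(columns)]
    for rec in records:
        lines.append(
            "\t".join(str(_format_value(col, rec.get(col))) for col in columns)
        )
    path.write_text("\n".join(lines) + "\n")
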