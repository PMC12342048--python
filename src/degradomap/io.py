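"""Table readers/writers binding the pipeline together.

The quantification-table dialect is TSV-first (peptide strings are tab-safe);
CSV is accepted via delimiter sniffing. Column names can be remapped so that
exports from different search engines parse identically.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .calling import PeptideObservation, RatioRecord, SiteCall
from .sequence import TERMINUS

__all__ = [
    "DEFAULT_COLUMNS",
    "QuantParseError",
    "read_quant_table",
    "observations_to_frame",
    "write_quant_table",
    "site_report_frame",
    "write_site_report",
    "read_site_report_json",
]

DEFAULT_COLUMNS = {
    "peptide": "peptide",
    "preceding": "preceding",
    "following": "following",
    "abundance_active": "abundance_active",
    "abundance_control": "abundance_control",
}


@dataclass
class QuantParseError:
    line: int
    message: str


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as handle:
        sample = handle.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def _parse_abundance(raw: object) -> float | None:
    if raw is None:
        return None
    text = str(raw).strip()
    if text in ("", "NA", "NaN", "nan", "None"):
        return None
    value = float(text)  # may raise ValueError
    if math.isnan(value):
        return None
    return value


def read_quant_table(
    path: str | Path,
    mapping: dict[str, str] | None = None,
    sep: str | None = None,
) -> tuple[list[PeptideObservation], list[QuantParseError]]:
    """Read a peptide quantification table.

    ``mapping`` maps the canonical field names (keys of
    :data:`DEFAULT_COLUMNS`) to the header names actually present. Malformed
    rows (negative or unparseable abundances, empty peptides) are rejected
    individually and reported with their line numbers; a missing required
    column raises immediately.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    columns = {**DEFAULT_COLUMNS, **(mapping or {})}
    sep = sep or _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [name for name in columns.values() if name not in frame.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path} (have {list(frame.columns)})")

    observations: list[PeptideObservation] = []
    errors: list[QuantParseError] = []
    for idx, row in enumerate(frame.to_dict("records")):
        line = idx + 2  # 1-based, after the header
        try:
            data = {name: row[columns[name]] for name in columns}
            observations.append(
                PeptideObservation(
                    peptide=str(data["peptide"]).strip(),
                    preceding=(str(data["preceding"]).strip() or TERMINUS),
                    following=(str(data["following"]).strip() or TERMINUS),
                    abundance_active=_parse_abundance(data["abundance_active"]),
                    abundance_control=_parse_abundance(data["abundance_control"]),
                )
            )
        except (ValueError, AttributeError) as exc:
            errors.append(QuantParseError(line=line, message=str(exc)))
    return observations, errors


def observations_to_frame(observations: list[PeptideObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide": [o.peptide for o in observations],
            "preceding": [o.preceding for o in observations],
            "following": [o.following for o in observations],
            "abundance_active": [o.abundance_active for o in observations],
            "abundance_control": [o.abundance_control for o in observations],
        }
    )


def write_quant_table(observations: list[PeptideObservation], path: str | Path) -> None:
    observations_to_frame(observations).to_csv(path, sep="\t", index=False)


def _record_json(rec: RatioRecord) -> dict:
    span = rec.span
    return {
        "peptide": rec.peptide,
        "preceding": rec.preceding,
        "following": rec.following,
        "detection_class": rec.detection_class,
        "ratio": rec.ratio,
        "log2_ratio": rec.log2_ratio,
        "ratio_converse": rec.ratio_converse,
        "z": rec.z,
        "z_converse": rec.z_converse,
        "tryptic_status": rec.tryptic_status,
        "span": [span.start, span.end] if span else None,
    }


def site_report_frame(sites: list[SiteCall]) -> pd.DataFrame:
    """Flat per-site summary table (one row per called site, position-sorted)."""
    rows = []
    for site in sites:
        classes = sorted({r.detection_class for r in site.supporting_semitryptic})
        rows.append(
            {
                "accession": site.accession,
                "p1_position": site.p1_position,
                "p1_residue": site.p1_residue,
                "p1prime_residue": site.p1prime_residue,
                "site": site.label,
                "region": site.region_label,
                "n_semitryptic": len(site.supporting_semitryptic),
                "n_spanning": len(site.spanning_tryptic),
                "n_corroborating": site.n_corroborating,
                "max_z": site.max_z,
                "detection_classes": ";".join(classes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "p1_position", "p1_residue", "p1prime_residue", "site",
            "region", "n_semitryptic", "n_spanning", "n_corroborating", "max_z",
            "detection_classes",
        ],
    )


def write_site_report(
    sites: list[SiteCall], out_dir: str | Path, stem: str = "sites"
) -> tuple[Path, Path]:
    """Write the deterministic TSV summary and the full JSON evidence report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / f"{stem}.tsv"
    json_path = out_dir / f"{stem}.json"
    site_report_frame(sites).to_csv(tsv_path, sep="\t", index=False)
    payload = [
        {
            "accession": site.accession,
            "p1_position": site.p1_position,
            "p1_residue": site.p1_residue,
            "p1prime_residue": site.p1prime_residue,
            "site": site.label,
            "region": site.region_label,
            "supporting_semitryptic": [_record_json(r) for r in site.supporting_semitryptic],
            "spanning_tryptic": [
                {**_record_json(r), "corroborating": flag}
                for r, flag in site.spanning_tryptic
            ],
        }
        for site in sites
    ]
    json_path.write_text(json.dumps(payload, indent=1))
    return tsv_path, json_path


def read_site_report_json(path: str | Path) -> list[dict]:
    """Read back a JSON site report (evidence preserved as plain dicts)."""
    return json.loads(Path(path).read_text())
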