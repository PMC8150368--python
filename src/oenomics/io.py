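"""Delimited-text interfaces: compound databases, peak tables, reports.

All formats are plain TSV so that runs are diffable and archivable:

* compound DB — one row per database entry (the panel-table layout);
* peak tables — one file per sample with columns ``mz, rt, area, intensity,
  iso1, iso2, fragments`` where ``iso1``/``iso2`` are the A+1/A+2 relative
  intensities and ``fragments`` is a ``;``-joined list of ``mz:intensity``
  pairs;
* hit reports, validation reports and marker tables mirror the appendix-style
  layouts (one row per compound with every criterion value).
"""

from __future__ import annotations

from pathlib import Path
from collections.abc import Mapping, Sequence

import pandas as pd
import yaml

from .chem import IsotopePattern
from .screening import PeakFeature, ScreeningHit
from .synth import build_compound_panel, CompoundSpec

__all__ = [
    "read_compound_db",
    "write_compound_db",
    "features_to_frame",
    "frame_to_features",
    "write_peak_tables",
    "read_peak_tables",
    "hits_to_frame",
    "write_summary",
    "read_summary",
]


def write_compound_db(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_compound_db(path: str | Path) -> list[CompoundSpec]:
    """Read a compound-database TSV into panel specs (validates each row)."""
    return build_compound_panel(pd.read_csv(path, sep="\t"))


def _format_fragments(feature: PeakFeature) -> str:
    return ";".join(f"{mz:.4f}:{inten:.1f}" for mz, inten in feature.msms_fragments)


def _parse_fragments(text: str) -> tuple[tuple[float, float], ...]:
    if not text or pd.isna(text):
        return ()
    out = []
    for token in str(text).split(";"):
        if not token:
            continue
        if ":" in token:
            mz, inten = token.split(":")
            out.append((float(mz), float(inten)))
        else:
            out.append((float(token), 1.0))
    return tuple(out)


def features_to_frame(features: Sequence[PeakFeature]) -> pd.DataFrame:
    rows = []
    for f in features:
        iso = f.isotope_envelope.peaks if f.isotope_envelope else ()
        rows.append(
            {
                "mz": f.mz,
                "rt": f.rt,
                "area": f.area,
                "intensity": f.intensity,
                "iso1": iso[1][1] if len(iso) > 1 else "",
                "iso2": iso[2][1] if len(iso) > 2 else "",
                "fragments": _format_fragments(f),
            }
        )
    return pd.DataFrame(rows)


def frame_to_features(frame: pd.DataFrame, sample_id: str) -> list[PeakFeature]:
    features = []
    for _, row in frame.iterrows():
        peaks = [(0.0, 1.0)]
        for k, col in enumerate(("iso1", "iso2"), start=1):
            value = row.get(col, "")
            if value != "" and not pd.isna(value):
                peaks.append((k * 1.0033548, float(value)))
        envelope = IsotopePattern(tuple(peaks)) if len(peaks) > 1 else None
        features.append(
            PeakFeature(
                sample_id=sample_id,
                mz=float(row["mz"]),
                rt=float(row["rt"]),
                area=float(row["area"]),
                intensity=float(row["intensity"]),
                isotope_envelope=envelope,
                msms_fragments=_parse_fragments(row.get("fragments", "")),
            )
        )
    return features


def write_peak_tables(
    features: Mapping[str, Sequence[PeakFeature]], directory: str | Path
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sample_id, sample_features in features.items():
        features_to_frame(sample_features).to_csv(
            directory / f"{sample_id}.tsv", sep="\t", index=False
        )


def read_peak_tables(directory: str | Path) -> dict[str, list[PeakFeature]]:
    directory = Path(directory)
    out: dict[str, list[PeakFeature]] = {}
    for path in sorted(directory.glob("*.tsv")):
        sample_id = path.stem
        out[sample_id] = frame_to_features(pd.read_csv(path, sep="\t"), sample_id)
    return out


def hits_to_frame(hits: Sequence[ScreeningHit]) -> pd.DataFrame:
    """Hit report: one row per (compound, sample) with all criterion values."""
    rows = []
    for h in hits:
        rows.append(
            {
                "compound": h.compound.name,
                "sample_id": h.sample_id,
                "role": h.compound.role,
                "mz_observed": h.feature.mz,
                "mz_theoretical": h.compound.theoretical_mz,
                "mass_error_mda": h.mass_error,
                "rt": h.feature.rt,
                "rt_error_min": h.rt_error if h.rt_error is not None else "",
                "msigma": h.msigma,
                "area": h.feature.area,
                "intensity": h.feature.intensity,
                "peak_score": h.peak_score,
                "n_fragments_matched": len(h.matched_fragments),
                "identification_level": h.identification_level,
            }
        )
    return pd.DataFrame(rows)


def write_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(summary, sort_keys=True))


def read_summary(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
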