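"""Trophic-level arithmetic on lens-chronology isotope values.

δ15N enriches by roughly one trophic discrimination factor (TDF,
default 3.4 permil) per trophic level, so an isotope change divided by
the TDF approximates a trophic-level change. A regression slope in
permil per mm converts via the average core-to-first-hard-layer
diameter span (0.67 mm to 2.96 mm). δ13C baseline means are corrected
upward by ~0.4 permil for consumer comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from isolens.lens_data import BaselineSample, LayerRecord

__all__ = [
    "TrophicConfig",
    "tl_change",
    "slope_tl_change",
    "lifetime_delta",
    "lifetime_delta_by_fish",
    "baseline_summary",
    "fin_lens_offset",
]


@dataclass(frozen=True)
class TrophicConfig:
    """Discrimination factors and reference lens diameters.

    ``tdf_n15``: δ15N enrichment per trophic level (permil).
    ``tdf_c13_correction``: added to baseline δ13C means when comparing
    consumers to baselines (permil). The reference diameters bound the
    exogenous-feeding span of the lens record: the core (earliest life)
    and the first hard layer (most recent hardened record).
    """

    tdf_n15: float = 3.4
    tdf_c13_correction: float = 0.4
    core_diameter_ref: float = 0.67
    hd_diameter_ref: float = 2.96

    def __post_init__(self) -> None:
        if self.tdf_n15 <= 0:
            raise ValueError("tdf_n15 must be positive")
        if not (self.hd_diameter_ref > self.core_diameter_ref):
            raise ValueError("hd_diameter_ref must exceed core_diameter_ref")


def tl_change(delta_d15N: float, cfg: TrophicConfig = TrophicConfig()) -> float:
    """Trophic-level change implied by a δ15N change (permil / TDF)."""
    return delta_d15N / cfg.tdf_n15


def slope_tl_change(slope: float, cfg: TrophicConfig = TrophicConfig()) -> float:
    """Trophic-level change implied by a δ15N-vs-diameter slope.

    The slope (permil per mm) is integrated over the core-to-HD
    diameter span and divided by the TDF.
    """
    return slope * (cfg.hd_diameter_ref - cfg.core_diameter_ref) / cfg.tdf_n15


def lifetime_delta(
    chronology: Sequence[LayerRecord], isotope: str = "d15N"
) -> float:
    """Within-individual lifetime isotope range (max minus min, permil).

    Computed over ALL layers including core and outermost, so interlayer
    variation counts even without a monotone trend; always >= 0 and
    invariant under layer reordering. Undefined (NaN) for a single
    layer.
    """
    if isotope not in ("d13C", "d15N"):
        raise ValueError(f"isotope must be 'd13C' or 'd15N', got {isotope!r}")
    vals = [getattr(r, isotope) for r in chronology if getattr(r, isotope) is not None]
    if len(vals) < 2:
        warnings.warn(
            "lifetime delta undefined with fewer than 2 layers", stacklevel=2
        )
        return float("nan")
    return float(max(vals) - min(vals))


def lifetime_delta_by_fish(
    layers: Sequence[LayerRecord], isotope: str = "d15N"
) -> pd.DataFrame:
    """Per-fish lifetime ranges plus per-lake means, as a tidy table."""
    frame_rows = []
    by_fish: dict[tuple[str, str, str], list[LayerRecord]] = {}
    for r in layers:
        if r.sample_kind != "primary":
            continue
        by_fish.setdefault((r.lake, r.species, r.fish_id), []).append(r)
    for (lake, species, fish), recs in by_fish.items():
        frame_rows.append(
            {
                "lake": lake,
                "species": species,
                "fish_id": fish,
                "isotope": isotope,
                "lifetime_delta": lifetime_delta(recs, isotope),
            }
        )
    return pd.DataFrame(frame_rows)


def baseline_summary(
    samples: Sequence[BaselineSample], cfg: TrophicConfig = TrophicConfig()
) -> pd.DataFrame:
    """Per lake x habitat x isotope mean and SD of baseline samples.

    δ13C rows additionally carry ``corrected_mean`` (mean plus the
    consumer TDF correction). Cells with a single sample report the
    value as the mean with a missing SD.
    """
    rows = []
    cells: dict[tuple[str, str], list[BaselineSample]] = {}
    for s in samples:
        cells.setdefault((s.lake, s.habitat), []).append(s)
    for (lake, habitat), recs in sorted(cells.items()):
        for iso in ("d13C", "d15N"):
            vals = np.array([getattr(r, iso) for r in recs], dtype=float)
            if vals.size == 0:
                warnings.warn(
                    f"no {iso} baseline samples for {lake}/{habitat}", stacklevel=2
                )
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
            row = {
                "lake": lake,
                "habitat": habitat,
                "isotope": iso,
                "n": int(vals.size),
                "mean": mean,
                "sd": sd,
            }
            if iso == "d13C":
                row["corrected_mean"] = mean + cfg.tdf_c13_correction
            rows.append(row)
    return pd.DataFrame(rows)


def fin_lens_offset(
    outermost: Mapping[str, tuple[float, float]],
    fin: Mapping[str, tuple[float, float]],
) -> dict[str, dict[str, float]]:
    """Outermost-lens-layer vs fin-tissue offset, paired by fish.

    Each mapping is fish_id -> (d13C, d15N). Returns per isotope the
    mean difference (outermost minus fin; negative means the lens reads
    lower) and the mean two-point SD across pairs. Fish present in only
    one mapping are skipped with a warning.
    """
    common = sorted(set(outermost) & set(fin))
    skipped = (set(outermost) | set(fin)) - set(common)
    if skipped:
        warnings.warn(
            f"unpaired fish skipped in fin-lens comparison: {sorted(skipped)}",
            stacklevel=2,
        )
    if not common:
        raise ValueError("no paired fish for the fin-lens comparison")
    out: dict[str, dict[str, float]] = {}
    for k, iso in enumerate(("d13C", "d15N")):
        diffs = [outermost[f][k] - fin[f][k] for f in common]
        sds = [float(np.std([outermost[f][k], fin[f][k]], ddof=1)) for f in common]
        out[iso] = {
            "mean_difference": float(np.mean(diffs)),
            "mean_sd": float(np.mean(sds)),
            "n_pairs": len(common),
        }
    return out
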