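"""Sediment pollution and ecological-risk indices with classification.

Implemented indices, all per sample (site-year) unless composite:

* Geoaccumulation index  Igeo = log2(C / (1.5 · GB)) — seven Müller grades.
* Enrichment factor      EF = (C/GB) / (C_Fe/GB_Fe), iron as the
  conservative reference element.
* Single pollution index SPI = C / GB.
* Single-metal ecological risk Er = Tr · SPI (Håkanson toxic-response
  coefficient Tr), and its sum RI over the ten metals.
* Toxic risk index       TRI_i = sqrt(((C/TEL)² + (C/PEL)²) / 2) per
  guideline metal, TRI = Σ TRI_i over the seven guideline metals.

Concentrations and backgrounds in mg·kg⁻¹ dry weight; all indices unitless.
No rounding happens inside computation; presentation rounding is applied
only at write-out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .data import GBTable, SamplePanel, ToxicityTables, ValidationError


class DomainError(ValueError):
    """An index was evaluated outside its mathematical domain."""


def igeo(c: float, gb: float) -> float:
    """Geoaccumulation index log2(C / (1.5·GB)).

    The 1.5 factor absorbs natural lithogenic fluctuation of the background.
    Strictly increasing in C, strictly decreasing in GB.
    """
    if not (c > 0 and gb > 0):
        raise DomainError(f"igeo requires C > 0 and GB > 0, got C={c}, GB={gb}")
    return math.log2(c / (1.5 * gb))


def igeo_class(value: float) -> int:
    """Müller grade 0–6: class 0 for Igeo ≤ 0, then upper-inclusive unit
    bins (0,1] → 1 … (4,5] → 5, anything above 5 → 6."""
    if not math.isfinite(value):
        raise DomainError(f"igeo_class requires a finite value, got {value}")
    if value <= 0:
        return 0
    return min(6, math.ceil(value))


def ef(c: float, gb: float, c_fe: float, gb_fe: float) -> float:
    """Enrichment factor: the metal's sample/background ratio normalised by
    the same ratio for iron."""
    for name, v in (("C", c), ("GB", gb), ("C_Fe", c_fe), ("GB_Fe", gb_fe)):
        if not v > 0:
            raise DomainError(f"ef requires {name} > 0, got {v}")
    return (c / gb) / (c_fe / gb_fe)


def spi(c: float, gb: float) -> float:
    """Single pollution index C / GB."""
    if not (c > 0 and gb > 0):
        raise DomainError(f"spi requires C > 0 and GB > 0, got C={c}, GB={gb}")
    return c / gb


def eri(analyte: str, spi_value: float, tox: ToxicityTables | None = None) -> float:
    """Single-metal ecological risk Er = Tr(analyte) × SPI."""
    tox = tox or ToxicityTables()
    try:
        tr = tox.tri_coeff[analyte]
    except KeyError:
        raise DomainError(f"no toxic-response coefficient for {analyte!r}") from None
    return tr * spi_value


def ri(eri_values: dict[str, float]) -> tuple[float, bool]:
    """Potential ecological risk RI = Σ Er over metals.

    Returns (value, complete) where ``complete`` records whether all ten
    metals contributed; partial panels are summed, not refused.
    """
    if not eri_values:
        raise DomainError("ri requires at least one Er value")
    complete = set(eri_values) >= set(reference.METALS)
    return float(sum(eri_values.values())), complete


def tri_i(c: float, tel: float, pel: float) -> float:
    """Per-metal toxic risk: root mean square of C/TEL and C/PEL."""
    if not (0 < tel < pel):
        raise ValidationError(f"require 0 < TEL < PEL, got ({tel}, {pel})")
    if c < 0:
        raise DomainError(f"tri_i requires C >= 0, got {c}")
    return math.sqrt(((c / tel) ** 2 + (c / pel) ** 2) / 2.0)


def tri(tri_i_values: dict[str, float]) -> tuple[float, bool]:
    """Toxic risk index TRI = Σ TRI_i over the guideline metals present."""
    if not tri_i_values:
        raise DomainError("tri requires at least one component")
    complete = set(tri_i_values) >= set(reference.GUIDELINES)
    return float(sum(tri_i_values.values())), complete


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered breakpoints mapping an index value to an integer class.

    ``right_closed=False`` (default): class k for breakpoints[k-1] ≤ v <
    breakpoints[k] — the lower bound of each class above the lowest is
    inclusive (RI = 150 falls in the moderate class).
    ``right_closed=True`` (Müller Igeo convention): class k for
    breakpoints[k-1] < v ≤ breakpoints[k].
    """

    index_name: str
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]
    right_closed: bool = False

    def __post_init__(self) -> None:
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValidationError(f"{self.index_name}: breakpoints must be strictly increasing")
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValidationError(
                f"{self.index_name}: need {len(self.breakpoints) + 1} labels, got {len(self.labels)}"
            )

    def classify(self, value: float) -> int:
        if not math.isfinite(value):
            raise DomainError(f"cannot classify non-finite value {value}")
        # side='right' counts breakpoints <= v: lower bounds inclusive;
        # side='left' counts breakpoints < v: upper bounds inclusive (Igeo)
        side = "left" if self.right_closed else "right"
        return int(np.searchsorted(np.asarray(self.breakpoints), value, side=side))

    def label(self, value: float) -> str:
        return self.labels[self.classify(value)]


IGEO_LABELS = (
    "unpolluted",
    "unpolluted to moderately polluted",
    "moderately polluted",
    "moderately to heavily polluted",
    "heavily polluted",
    "heavily to extremely polluted",
    "extremely polluted",
)


def default_schemes() -> dict[str, ClassificationScheme]:
    """The classification schemes used when no override is supplied."""
    return {
        "Igeo": ClassificationScheme(
            "Igeo", (0.0, 1.0, 2.0, 3.0, 4.0, 5.0), IGEO_LABELS, right_closed=True
        ),
        "EF": ClassificationScheme(
            "EF",
            (2.0, 5.0, 20.0, 40.0),
            ("minimal", "moderate", "significant", "very high", "extremely high"),
        ),
        "Eri": ClassificationScheme(
            "Eri",
            (40.0, 80.0, 160.0, 320.0),
            ("low", "moderate", "considerable", "high", "very high"),
        ),
        "RI": ClassificationScheme(
            "RI", (150.0, 300.0, 600.0), ("low", "moderate", "high", "very high")
        ),
        "TRI": ClassificationScheme(
            "TRI",
            (5.0, 10.0, 15.0, 20.0),
            ("no toxic risk", "low", "moderate", "considerable", "very high"),
        ),
    }


def classify(index_name: str, value: float, schemes: dict[str, ClassificationScheme] | None = None) -> tuple[int, str]:
    """Class number and text label of ``value`` under the scheme for
    ``index_name`` (TRI_i values use the per-metal-free TRI scheme only when
    explicitly requested; per-metal TRI_i rows are left unclassified by
    compute_all)."""
    schemes = schemes or default_schemes()
    try:
        scheme = schemes[index_name]
    except KeyError:
        raise DomainError(f"no classification scheme for index {index_name!r}") from None
    k = scheme.classify(value)
    return k, scheme.labels[k]


def compute_all(
    panel: SamplePanel,
    gb: GBTable,
    tox: ToxicityTables | None = None,
    schemes: dict[str, ClassificationScheme] | None = None,
) -> pd.DataFrame:
    """Per-sample index table.

    For every (site, year): per-metal Igeo, EF (when an Fe record exists),
    SPI, Er and TRI_i, plus composite RI and TRI rows (analyte='ALL') with a
    completeness flag.  Deterministic given its inputs.

    Raises on any (site, analyte) pair lacking a geochemical background.
    """
    tox = tox or ToxicityTables()
    schemes = schemes or default_schemes()

    metals = [a for a in reference.METALS]
    needed = {
        (int(s), a)
        for s, a in panel.data[panel.data["analyte"].isin(metals + ["Fe"])][
            ["site_id", "analyte"]
        ].itertuples(index=False)
    }
    missing = sorted(p for p in needed if p not in gb.entries)
    if missing:
        raise ValidationError(f"missing geochemical background for: {missing[:20]}")

    wide = panel.pivot(metals + ["Fe"]) if len(panel) else pd.DataFrame()
    rows: list[dict] = []
    for (site, year), sample in wide.iterrows():
        fe = sample.get("Fe", np.nan)
        gb_fe = gb.entries.get((site, "Fe"))
        eri_parts: dict[str, float] = {}
        tri_parts: dict[str, float] = {}
        for analyte in metals:
            c = sample.get(analyte, np.nan)
            if not np.isfinite(c):
                continue
            g = gb.get(site, analyte)
            v_igeo = igeo(c, g)
            v_spi = spi(c, g)
            v_eri = eri(analyte, v_spi, tox)
            eri_parts[analyte] = v_eri
            k_igeo = igeo_class(v_igeo)
            rows.append(
                {"site_id": site, "year": year, "analyte": analyte, "index": "Igeo",
                 "value": v_igeo, "class": k_igeo, "label": IGEO_LABELS[k_igeo]}
            )
            rows.append(
                {"site_id": site, "year": year, "analyte": analyte, "index": "SPI",
                 "value": v_spi, "class": None, "label": ""}
            )
            k_eri, lab_eri = classify("Eri", v_eri, schemes)
            rows.append(
                {"site_id": site, "year": year, "analyte": analyte, "index": "Eri",
                 "value": v_eri, "class": k_eri, "label": lab_eri}
            )
            if np.isfinite(fe) and gb_fe is not None:
                v_ef = ef(c, g, fe, gb_fe)
                k_ef, lab_ef = classify("EF", v_ef, schemes)
                rows.append(
                    {"site_id": site, "year": year, "analyte": analyte, "index": "EF",
                     "value": v_ef, "class": k_ef, "label": lab_ef}
                )
            if analyte in tox.guidelines:
                tel, pel = tox.guidelines[analyte]
                v_tri = tri_i(c, tel, pel)
                tri_parts[analyte] = v_tri
                rows.append(
                    {"site_id": site, "year": year, "analyte": analyte, "index": "TRI_i",
                     "value": v_tri, "class": None, "label": ""}
                )
        if eri_parts:
            v_ri, complete = ri(eri_parts)
            k_ri, lab_ri = classify("RI", v_ri, schemes)
            rows.append(
                {"site_id": site, "year": year, "analyte": "ALL", "index": "RI",
                 "value": v_ri, "class": k_ri,
                 "label": lab_ri if complete else f"{lab_ri} (incomplete)"}
            )
        if tri_parts:
            v_tri, complete = tri(tri_parts)
            k_tri, lab_tri = classify("TRI", v_tri, schemes)
            rows.append(
                {"site_id": site, "year": year, "analyte": "ALL", "index": "TRI",
                 "value": v_tri, "class": k_tri,
                 "label": lab_tri if complete else f"{lab_tri} (incomplete)"}
            )
    columns = ["site_id", "year", "analyte", "index", "value", "class", "label"]
    return pd.DataFrame(rows, columns=columns)
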