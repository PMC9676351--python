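"""Metabolite chemical-shift region table.

Serum 1H NMR resonances are quantified by integrating the spectrum over
fixed chemical-shift windows.  The default panel holds 28 metabolites with
literature shift windows (600 MHz, serum, pH ~7.4); nine of them carry
nonzero synthetic stage effects: in advanced disease 3-hydroxybutyrate,
citrate, N,N-dimethylglycine and phenylalanine rise while leucine,
isoleucine, valine, acetate and histidine fall.  Effects are expressed as
log fold changes so a negative value means a lower serum level.

All windows lie inside the analyzed range [0.2, 10.0] ppm and avoid the
residual-water window (4.42-5.10 ppm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

PPM_RANGE = (0.2, 10.0)
WATER_REGION = (4.42, 5.10)


@dataclass(frozen=True)
class MetaboliteSpec:
    """One metabolite: shift windows, abundance and synthetic effect sizes.

    Parameters
    ----------
    name
        Metabolite name.
    ppm_regions
        Chemical-shift windows ``(lo, hi)`` in ppm whose integrals sum to
        the metabolite's signal.
    base_concentration
        Mean abundance in arbitrary integral units; must be positive.
    abc_log_fold_change
        Log fold change in advanced (metastatic) vs early relapse-free
        disease.
    relapse_log_fold_change
        Log fold change in early patients who later relapse, same sign
        convention.
    """

    name: str
    ppm_regions: tuple[tuple[float, float], ...]
    base_concentration: float
    abc_log_fold_change: float = 0.0
    relapse_log_fold_change: float = 0.0

    def __post_init__(self) -> None:
        if self.base_concentration <= 0:
            raise ConfigurationError(
                f"{self.name}: base_concentration must be positive"
            )
        if not self.ppm_regions:
            raise ConfigurationError(f"{self.name}: at least one ppm region required")
        for lo, hi in self.ppm_regions:
            if not (PPM_RANGE[0] <= lo < hi <= PPM_RANGE[1]):
                raise ConfigurationError(
                    f"{self.name}: region ({lo}, {hi}) outside {PPM_RANGE}"
                )
            if lo < WATER_REGION[1] and hi > WATER_REGION[0]:
                raise ConfigurationError(
                    f"{self.name}: region ({lo}, {hi}) overlaps the water "
                    f"exclusion window {WATER_REGION}"
                )

    @property
    def total_width(self) -> float:
        return sum(hi - lo for lo, hi in self.ppm_regions)


def _m(name, regions, base, abc=0.0, rel=0.0):
    return MetaboliteSpec(name, tuple(regions), base, abc, rel)


#: Default 28-metabolite panel.  The nine stage-associated metabolites carry
#: |log FC| = 0.30 for advanced disease; relapsed early patients get half
#: that shift except phenylalanine and acetate, whose trend does not carry
#: over to relapse.
DEFAULT_PANEL: tuple[MetaboliteSpec, ...] = (
    _m("leucine", [(0.94, 0.97)], 0.8, -0.30, -0.15),
    _m("isoleucine", [(0.99, 1.02)], 0.5, -0.30, -0.15),
    _m("valine", [(1.03, 1.05)], 0.7, -0.30, -0.15),
    _m("3-hydroxybutyrate", [(1.18, 1.21), (2.29, 2.33)], 0.5, +0.30, +0.15),
    _m("lactate", [(1.31, 1.34), (4.10, 4.13)], 2.5),
    _m("alanine", [(1.46, 1.49)], 1.2),
    _m("arginine", [(1.63, 1.67)], 0.4),
    _m("lysine", [(1.70, 1.74)], 0.6),
    _m("acetate", [(1.90, 1.93)], 0.4, -0.30, 0.0),
    _m("N-acetyl-glycoproteins", [(2.02, 2.06)], 1.5),
    _m("glutamate", [(2.07, 2.10)], 0.6),
    _m("methionine", [(2.12, 2.15)], 0.3),
    _m("pyruvate", [(2.36, 2.40)], 0.3),
    _m("glutamine", [(2.43, 2.47)], 1.0),
    _m("citrate", [(2.52, 2.56), (2.64, 2.68)], 0.6, +0.30, +0.15),
    _m("N,N-dimethylglycine", [(2.91, 2.93)], 0.2, +0.30, +0.15),
    _m("creatine", [(3.02, 3.05)], 0.4),
    _m("choline", [(3.20, 3.23)], 0.5),
    _m("trimethylamine-N-oxide", [(3.25, 3.28)], 0.4),
    _m("glucose", [(3.44, 3.50), (5.22, 5.26)], 5.0),
    _m("glycine", [(3.54, 3.57)], 0.8),
    _m("glycerol", [(3.63, 3.66)], 0.7),
    _m("creatinine", [(4.04, 4.07)], 0.3),
    _m("tyrosine", [(6.88, 6.91)], 0.3),
    _m("1-methylhistidine", [(7.18, 7.21)], 0.15),
    _m("histidine", [(7.05, 7.09), (7.75, 7.79)], 0.4, -0.30, -0.15),
    _m("phenylalanine", [(7.36, 7.39)], 0.3, +0.30, 0.0),
    _m("formate", [(8.44, 8.47)], 0.1),
)

#: Names of the nine metabolites reported as stage-associated.
STAGE_ASSOCIATED = tuple(
    m.name for m in DEFAULT_PANEL if m.abc_log_fold_change != 0.0
)


def panel_to_frame(panel=DEFAULT_PANEL):
    """Region table as a DataFrame with one row per (metabolite, region)."""
    import pandas as pd

    rows = []
    for m in panel:
        for lo, hi in m.ppm_regions:
            rows.append(
                {
                    "metabolite": m.name,
                    "lo_ppm": lo,
                    "hi_ppm": hi,
                    "base_concentration": m.base_concentration,
                    "abc_log_fold_change": m.abc_log_fold_change,
                    "relapse_log_fold_change": m.relapse_log_fold_change,
                }
            )
    return pd.DataFrame(rows)


def panel_from_frame(df) -> tuple[MetaboliteSpec, ...]:
    """Inverse of :func:`panel_to_frame`."""
    specs = []
    for name, grp in df.groupby("metabolite", sort=False):
        first = grp.iloc[0]
        specs.append(
            MetaboliteSpec(
                name=name,
                ppm_regions=tuple(
                    (float(r.lo_ppm), float(r.hi_ppm)) for r in grp.itertuples()
                ),
                base_concentration=float(first["base_concentration"]),
                abc_log_fold_change=float(first["abc_log_fold_change"]),
                relapse_log_fold_change=float(first["relapse_log_fold_change"]),
            )
        )
    return tuple(specs)
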