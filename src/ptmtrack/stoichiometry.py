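"""Back-of-envelope molecular composition of PTM-enriched territories.

Deterministic calculators for (i) the expected molecular content of one
enriched territory (a territory of ~1 um^2 cross-section occupies roughly
1/200th of a ~200 um^3 nucleus), (ii) per-cell Fab binding-site budgets and
the implied bound fraction, and (iii) the dye degree of labeling (DOL) of a
conjugated Fab from its absorbance spectrum,

    DOL = (eps_Fab / eps_dye) * 1 / (A280/Adye - CF).

Counts are reported as exact floats of the parameter arithmetic; rounding
to presentation precision is left to the caller.

A note on internal consistency: with 60e6 nucleosomes/cell, two H3 tails
each and a 2% H3K27ac fraction, the potential tail sites number 120e6 and
the marked (Fab-bindable) sites 2% of that, i.e. 2.4e6.  Accounts that
quote ~4.4e6 marked sites for the same inputs are not reproducible from
this arithmetic; the calculator always reports the formula value.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError


@dataclass(frozen=True)
class CompositionParams:
    """Defaults follow the published territory/abundance assumptions."""

    nucleus_volume_um3: float = 200.0
    site_volume_fraction: float = 1.0 / 200.0
    nucleosomes_per_cell: float = 6.0e7
    h3k27ac_fraction: float = 0.02
    h3_per_nucleosome: int = 2
    initiated_rnap2_per_cell: float = 1.0e5
    heptads_per_rnap2: int = 52
    fab_loaded_per_cell: float = 1.0e6
    fab_nuclear_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("nucleus_volume_um3", "site_volume_fraction",
                     "nucleosomes_per_cell", "h3_per_nucleosome",
                     "heptads_per_rnap2", "fab_loaded_per_cell"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("site_volume_fraction", "h3k27ac_fraction",
                     "fab_nuclear_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ParameterError(f"{name} must lie in (0, 1]")
        if self.initiated_rnap2_per_cell < 0:
            raise ParameterError("initiated_rnap2_per_cell must be >= 0")


@dataclass(frozen=True)
class SiteComposition:
    nucleosomes: float
    acetylated_nucleosomes: float
    h3k27ac_sites: float        # potential tail sites on marked nucleosomes
    initiated_rnap2: float
    ser5ph_sites: float


@dataclass(frozen=True)
class CellBindingSites:
    ser5ph_sites: float
    h3_tail_sites: float        # all potential H3K27ac tail sites
    h3k27ac_marked_sites: float  # tails actually carrying the mark
    fab_in_nucleus: float
    bound_fraction_pct: float   # nuclear Fab / Ser5ph sites, percent


def site_composition(params: CompositionParams = CompositionParams()
                     ) -> SiteComposition:
    """Expected molecular content of one average enriched territory."""
    nucleosomes = params.nucleosomes_per_cell * params.site_volume_fraction
    acetylated = nucleosomes * params.h3k27ac_fraction
    rnap2 = params.initiated_rnap2_per_cell * params.site_volume_fraction
    return SiteComposition(
        nucleosomes=nucleosomes,
        acetylated_nucleosomes=acetylated,
        h3k27ac_sites=acetylated * params.h3_per_nucleosome,
        initiated_rnap2=rnap2,
        ser5ph_sites=rnap2 * params.heptads_per_rnap2,
    )


def cell_binding_sites(params: CompositionParams = CompositionParams()
                       ) -> CellBindingSites:
    """Per-cell Fab binding-site budget and bound fraction."""
    ser5ph = params.initiated_rnap2_per_cell * params.heptads_per_rnap2
    h3_tails = params.nucleosomes_per_cell * params.h3_per_nucleosome
    fab_nuclear = params.fab_loaded_per_cell * params.fab_nuclear_fraction
    if ser5ph <= 0:
        raise ParameterError(
            "bound fraction undefined with zero Ser5ph sites")
    return CellBindingSites(
        ser5ph_sites=ser5ph,
        h3_tail_sites=h3_tails,
        h3k27ac_marked_sites=h3_tails * params.h3k27ac_fraction,
        fab_in_nucleus=fab_nuclear,
        bound_fraction_pct=100.0 * fab_nuclear / ser5ph,
    )


#: Extinction coefficients in 1/(M cm).
EPS_FAB = 70_000.0
EPS_AF488 = 71_000.0
EPS_CF640 = 105_000.0


@dataclass(frozen=True)
class DOLParams:
    eps_fab: float = EPS_FAB
    eps_dye: float = EPS_AF488
    a280: float = 1.0           # absorbance of the conjugate at 280 nm
    a_dye: float = 1.0          # absorbance at the dye's peak
    cf: float = 0.11            # dye correction factor A280/Apeak (dye alone)

    def __post_init__(self) -> None:
        if self.eps_fab <= 0 or self.eps_dye <= 0:
            raise ParameterError("extinction coefficients must be positive")
        if self.a280 < 0 or self.a_dye < 0:
            raise ParameterError("absorbances must be nonnegative")


def degree_of_labeling(params: DOLParams) -> float:
    """Average dyes conjugated per Fab from the absorbance ratio."""
    if params.a_dye == 0:
        raise ParameterError("a_dye must be positive")
    ratio = params.a280 / params.a_dye
    if ratio <= params.cf:
        raise ParameterError(
            f"A280/Adye = {ratio:.3g} must exceed the correction factor "
            f"{params.cf:.3g}")
    return (params.eps_fab / params.eps_dye) / (ratio - params.cf)
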