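"""MS/MS annotation for two-acyl aminolipids.

The evidence model for a sulfur-containing aminolipid (SAL) in negative-mode
MSn is: (i) an [M-H]- precursor; (ii) an MS2 neutral loss matching a fatty
acid (the ester-linked acyl, e.g. the 282 Da loss of an 18:1 free acid);
(iii) low-mass diagnostic sulfonate ions (SO3-, HSO3-, SO2-, HSO2-); (iv) a
deprotonated, dehydrated head-group ion (aminopropane sulfonate at m/z ~136);
and (v) for 15N-labelled cultures, a one-nitrogen precursor mass shift.
This module turns peak lists into those annotations and assembles ranked
whole-lipid structure hypotheses from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from . import formula as fm
from .formula import (
    DEFAULT_MASS_TABLE,
    FormulaCandidate,
    add_formulas,
    enumerate_formulas,
    format_formula,
    monoisotopic_mass,
    nominal_mass,
    ppm_error,
    subtract_formulas,
)

__all__ = [
    "Peak",
    "Spectrum",
    "AcylSpec",
    "FragmentAnnotation",
    "FragmentationTree",
    "LipidHypothesis",
    "SulfonateReport",
    "N15_MASS_SHIFT",
    "DIAGNOSTIC_SULFONATE_IONS",
    "lock_mass_correct",
    "build_acyl_library",
    "match_neutral_losses",
    "detect_sulfonate_signature",
    "assign_head_group",
    "infer_label_count",
    "build_fragmentation_tree",
    "propose_structure",
]

#: mass difference between 15N and 14N in Da
N15_MASS_SHIFT = 0.9970349

#: negative-mode diagnostic ions for a sulfonate head group
DIAGNOSTIC_SULFONATE_IONS = ("SO3", "HSO3", "SO2", "HSO2")

#: default bounds used for formula assignment (wide CHNOPS search; the O
#: bound is symmetric with C/H/N since sulfonates require oxygen)
DEFAULT_BOUNDS = {
    "C": (0, 100),
    "H": (0, 100),
    "N": (0, 100),
    "O": (0, 100),
    "S": (0, 4),
    "P": (0, 1),
}


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 0.0

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"negative intensity {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """A single-level peak list (MS1/MS2/MS3)."""

    level: int
    peaks: tuple[Peak, ...]
    precursor_mz: float | None = None
    collision_energy: float | None = None
    polarity: str = "-"

    def __post_init__(self):
        if self.level not in (1, 2, 3):
            raise ValueError(f"MS level must be 1, 2 or 3, got {self.level}")
        if self.level > 1 and self.precursor_mz is None:
            raise ValueError(f"MS{self.level} spectrum requires a precursor m/z")
        if self.polarity not in ("+", "-"):
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")
        object.__setattr__(
            self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz))
        )

    @property
    def mz_values(self) -> tuple[float, ...]:
        return tuple(p.mz for p in self.peaks)


_ACYL_SPECIES = ("free_acid", "ketene", "carboxylate_anion")


@dataclass(frozen=True)
class AcylSpec:
    """A fatty acyl of chain length c, d double bonds, x in {0,1} hydroxyls.

    Species formulas: free acid C_c H_{2c-2d} O_{2+x}; ketene (acid minus
    water) C_c H_{2c-2d-2} O_{1+x}; carboxylate anion C_c H_{2c-2d-1} O_{2+x}.
    """

    c: int
    d: int
    x: int = 0
    species: str = "free_acid"

    def __post_init__(self):
        if self.c < 2:
            raise ValueError(f"chain length must be >= 2, got {self.c}")
        if not (0 <= self.d <= 6):
            raise ValueError(f"double-bond count out of range: {self.d}")
        if self.x not in (0, 1):
            raise ValueError(f"hydroxyl count must be 0 or 1, got {self.x}")
        if self.species not in _ACYL_SPECIES:
            raise ValueError(f"unknown acyl species {self.species!r}")
        if self.formula()["H"] <= 0:
            raise ValueError(f"over-unsaturated acyl: {self}")

    def formula(self) -> dict:
        h = {"free_acid": 2 * self.c - 2 * self.d,
             "ketene": 2 * self.c - 2 * self.d - 2,
             "carboxylate_anion": 2 * self.c - 2 * self.d - 1}[self.species]
        o = {"free_acid": 2, "ketene": 1, "carboxylate_anion": 2}[self.species] + self.x
        return {"C": self.c, "H": h, "O": o}

    def mass(self, table=DEFAULT_MASS_TABLE) -> float:
        return monoisotopic_mass(self.formula(), table)

    @property
    def name(self) -> str:
        hydroxy = "3-OH-" if self.x else ""
        return f"{hydroxy}{self.c}:{self.d} {self.species.replace('_', ' ')}"


@dataclass(frozen=True)
class FragmentAnnotation:
    peak: Peak
    kind: str  # neutral_loss | diagnostic_ion | head_group | unassigned
    assigned_formula: dict | None = None
    acyl: AcylSpec | None = None
    ppm_error: float | None = None
    note: str = ""


@dataclass
class SulfonateReport:
    """Per-ion hits for the four sulfonate diagnostics plus the overall call."""

    hits: dict  # ion formula string -> (peak, |ppm|) or None
    present: bool

    @property
    def n_hits(self) -> int:
        return sum(1 for v in self.hits.values() if v is not None)


@dataclass
class FragmentationTree:
    """Precursor->fragment linkage across MS levels."""

    nodes: list  # (mz, level)
    edges: list  # (parent_mz, child_mz, loss_formula or None, loss_name)
    orphans: list = field(default_factory=list)  # MS3 precursors with no MS2 peak


@dataclass(frozen=True)
class LipidHypothesis:
    """A head group plus amide- and ester-linked acyls explaining a precursor.

    ``total_deprotonated_formula`` is head + amide acyl + ester acyl (both as
    free acids) minus two waters (amide and ester condensations) minus one H
    (deprotonation).  ``isomer_ambiguous`` records that MS cannot place the
    amino group (2- vs 3-aminopropane sulfonic acid).
    """

    head_group_neutral: dict
    amide_acyl: AcylSpec
    ester_acyl: AcylSpec
    total_deprotonated_formula: dict
    theoretical_mh_minus: float
    ppm_vs_precursor: float
    isomer_ambiguous: bool = True


def lock_mass_correct(
    spectrum: Spectrum,
    observed_lock: float,
    lock_formula,
    table=DEFAULT_MASS_TABLE,
    max_deviation_ppm: float = 200.0,
) -> Spectrum:
    """Rescale the m/z axis so the lock peak lands on its theoretical mass.

    Every peak m/z is multiplied by theoretical/observed; intensities are
    untouched.  An observed lock further than ``max_deviation_ppm`` from the
    theoretical value is rejected as a mis-picked lock peak.
    """
    theoretical = monoisotopic_mass(lock_formula, table)
    deviation = ppm_error(observed_lock, theoretical)
    if abs(deviation) > max_deviation_ppm:
        raise ValueError(
            f"observed lock {observed_lock} deviates {deviation:.1f} ppm from "
            f"{format_formula(fm._as_formula(lock_formula))} "
            f"({theoretical:.4f}); limit {max_deviation_ppm} ppm"
        )
    ratio = theoretical / observed_lock
    peaks = tuple(Peak(p.mz * ratio, p.intensity) for p in spectrum.peaks)
    precursor = spectrum.precursor_mz * ratio if spectrum.precursor_mz else None
    return replace(spectrum, peaks=peaks, precursor_mz=precursor)


def build_acyl_library(
    c_range: Iterable[int],
    d_range: Iterable[int],
    hydroxyl_range: Iterable[int] = (0,),
    species: Iterable[str] = _ACYL_SPECIES,
    table=DEFAULT_MASS_TABLE,
) -> list[tuple[AcylSpec, float, int]]:
    """(AcylSpec, monoisotopic mass, nominal mass) for every combination."""
    c_range, d_range, hydroxyl_range = list(c_range), list(d_range), list(hydroxyl_range)
    if not c_range or not d_range or not hydroxyl_range:
        raise ValueError("acyl library ranges must be non-empty")
    out, seen = [], set()
    for sp in species:
        for c in c_range:
            for d in d_range:
                for x in hydroxyl_range:
                    try:
                        spec = AcylSpec(c=c, d=d, x=x, species=sp)
                    except ValueError:  # over-unsaturated for this species
                        continue
                    if spec in seen:
                        continue
                    seen.add(spec)
                    out.append(
                        (spec, spec.mass(table), nominal_mass(spec.formula(), table))
                    )
    return out


def match_neutral_losses(
    spectrum: Spectrum,
    library: Sequence[tuple[AcylSpec, float, int]],
    tolerance_ppm: float = 100.0,
    precursor: float | None = None,
    tolerance_da: float | None = None,
) -> list[FragmentAnnotation]:
    """Match precursor-minus-peak mass differences against an acyl library.

    The loss deviation is measured in Da and reported as ppm relative to the
    theoretical loss mass.  The acceptance window is either ``tolerance_ppm``
    on the loss mass or, when ``tolerance_da`` is given, an absolute window —
    statistically the honest choice, since a loss is the difference of two
    measured m/z values and its absolute error does not shrink with the loss
    mass.  Each peak gets its single best (smallest deviation) library match,
    or an ``unassigned`` annotation.  Peaks at or above the precursor
    (isotope/noise) are annotated unassigned with a warning note.
    """
    precursor = precursor if precursor is not None else spectrum.precursor_mz
    if precursor is None:
        raise ValueError("neutral-loss matching needs a precursor m/z")
    out = []
    for peak in spectrum.peaks:
        delta = precursor - peak.mz
        if delta <= 0:
            out.append(
                FragmentAnnotation(
                    peak, "unassigned", note="peak at/above precursor m/z"
                )
            )
            continue
        best = None
        for spec, mass, _nominal in library:
            dev_da = delta - mass
            within = (
                abs(dev_da) <= tolerance_da
                if tolerance_da is not None
                else abs(ppm_error(delta, mass)) <= tolerance_ppm
            )
            if within and (best is None or abs(dev_da) < abs(best[1])):
                best = (spec, dev_da)
        if best is None:
            out.append(FragmentAnnotation(peak, "unassigned"))
        else:
            spec, dev_da = best
            out.append(
                FragmentAnnotation(
                    peak,
                    "neutral_loss",
                    assigned_formula=spec.formula(),
                    acyl=spec,
                    ppm_error=ppm_error(delta, spec.mass()),
                    note=f"loss of {spec.name}",
                )
            )
    return out


def detect_sulfonate_signature(
    spectrum: Spectrum,
    tolerance_ppm: float = 100.0,
    table=DEFAULT_MASS_TABLE,
) -> SulfonateReport:
    """Look for the four low-mass sulfonate fragment ions.

    The overall signature is called present when at least 2 of the 4 ions
    (SO3-, HSO3-, SO2-, HSO2-) are found within tolerance.
    """
    if spectrum.polarity != "-":
        raise ValueError("sulfonate diagnostics are negative-mode ions")
    hits = {}
    for ion in DIAGNOSTIC_SULFONATE_IONS:
        theo = monoisotopic_mass(ion, table)
        best = None
        for peak in spectrum.peaks:
            dev = ppm_error(peak.mz, theo)
            if abs(dev) <= tolerance_ppm and (best is None or abs(dev) < abs(best[1])):
                best = (peak, dev)
        hits[ion] = best
    n = sum(1 for v in hits.values() if v is not None)
    return SulfonateReport(hits=hits, present=n >= 2)


def assign_head_group(
    spectrum: Spectrum,
    mz_window: tuple[float, float],
    bounds: Mapping[str, tuple[int, int]] = DEFAULT_BOUNDS,
    tolerance_ppm: float = 100.0,
    must_contain: Iterable[str] = ("N", "S"),
    must_not_contain: Iterable[str] = (),
    even_electron: bool = True,
    require_rdbe_nonneg: bool = True,
    table=DEFAULT_MASS_TABLE,
) -> dict:
    """Formula candidates for peaks inside a head-group m/z window.

    Delegates to the formula enumerator, keeps candidates containing every
    element in ``must_contain`` (an aminosulfonate head must carry both N
    and S) and none of ``must_not_contain``, then applies chemical
    plausibility: a CID head-group fragment is a closed-shell (even-electron)
    anion, whose atomic composition has half-integer RDBE, and negative RDBE
    compositions are not valence-realizable.  Both filters can be switched
    off.  Returns {peak m/z: ranked candidate list}.
    """
    lo, hi = mz_window
    must = set(must_contain)
    forbid = set(must_not_contain)
    out: dict[float, list[FormulaCandidate]] = {}
    for peak in spectrum.peaks:
        if not (lo <= peak.mz <= hi):
            continue
        cands = enumerate_formulas(peak.mz, tolerance_ppm, bounds, table)
        kept = []
        for c in cands:
            if not all(c.formula.get(el, 0) > 0 for el in must):
                continue
            if any(c.formula.get(el, 0) > 0 for el in forbid):
                continue
            if even_electron and c.rdbe % 1 != 0.5:
                continue
            if require_rdbe_nonneg and c.rdbe < 0:
                continue
            kept.append(c)
        out[peak.mz] = kept
    return out


def infer_label_count(
    mz_unlabeled: float,
    mz_labeled: float,
    isotope_delta: float = N15_MASS_SHIFT,
) -> tuple[int, float]:
    """Number of labelled atoms from an isotope-feeding mass shift.

    Returns (count, residual Da) where count = round(shift / delta) and the
    residual is the leftover after subtracting count deltas — a QC number
    (instrument deviation), not part of the decision.
    """
    if isotope_delta <= 0:
        raise ValueError(f"isotope delta must be positive, got {isotope_delta}")
    shift = mz_labeled - mz_unlabeled
    if shift < 0:
        raise ValueError(f"negative label shift: {shift:.4f} Da")
    count = round(shift / isotope_delta)
    return count, shift - count * isotope_delta


def build_fragmentation_tree(
    spectra: Sequence[Spectrum],
    link_tolerance_ppm: float = 20.0,
    library: Sequence[tuple[AcylSpec, float, int]] | None = None,
    loss_tolerance_ppm: float = 100.0,
) -> FragmentationTree:
    """Link MS3 precursors to MS2 peaks and label edges with neutral losses."""
    ms2 = [s for s in spectra if s.level == 2]
    ms3 = [s for s in spectra if s.level == 3]
    tree = FragmentationTree(nodes=[], edges=[])
    for s in ms2:
        tree.nodes.append((s.precursor_mz, 2))
    for s3 in ms3:
        parent = None
        for s2 in ms2:
            for peak in s2.peaks:
                if abs(ppm_error(s3.precursor_mz, peak.mz)) <= link_tolerance_ppm:
                    parent = s2
                    break
            if parent:
                break
        if parent is None:
            tree.orphans.append(s3.precursor_mz)
            continue
        tree.nodes.append((s3.precursor_mz, 3))
        loss_formula, loss_name = None, "unassigned"
        if library:
            ann = match_neutral_losses(
                Spectrum(level=2, peaks=(Peak(s3.precursor_mz),),
                         precursor_mz=parent.precursor_mz),
                library,
                tolerance_ppm=loss_tolerance_ppm,
            )[0]
            if ann.kind == "neutral_loss":
                loss_formula, loss_name = ann.assigned_formula, ann.acyl.name
        tree.edges.append(
            (parent.precursor_mz, s3.precursor_mz, loss_formula, loss_name)
        )
    return tree


# Head fragment chemistry: amide cleavage releases the head group as a
# doubly dehydrogenated, deprotonated ion — aminopropane sulfonic acid
# C3H9NO3S is observed as C3H6NO3S- at m/z ~136 (the carbonyl oxygen leaves
# with the acyl side; the head keeps all three sulfonate oxygens and loses
# two hydrogens to the new unsaturation plus one to deprotonation).
_HEAD_ION_TO_NEUTRAL = {"H": 3}


def head_ion_to_neutral(head_ion_formula) -> dict:
    """Neutral head-group formula from its amide-cleavage fragment ion."""
    return add_formulas(head_ion_formula, _HEAD_ION_TO_NEUTRAL)


def assemble_hypothesis(
    head_neutral,
    amide: AcylSpec,
    ester: AcylSpec,
    precursor_mz: float,
    table=DEFAULT_MASS_TABLE,
) -> LipidHypothesis:
    """Build one hypothesis by mass additivity: head + 2 acyls - 2 H2O - H."""
    water = {"H": 2, "O": 1}
    head_neutral = fm._as_formula(head_neutral)
    total = subtract_formulas(
        add_formulas(head_neutral, amide.formula(), ester.formula()),
        water, water, {"H": 1},
    )
    theo = monoisotopic_mass(total, table)
    return LipidHypothesis(
        head_group_neutral=head_neutral,
        amide_acyl=amide,
        ester_acyl=ester,
        total_deprotonated_formula=total,
        theoretical_mh_minus=theo,
        ppm_vs_precursor=ppm_error(precursor_mz, theo),
    )


def propose_structure(
    precursor_mz: float,
    loss_annotations: Sequence[FragmentAnnotation],
    head_candidates: Sequence[FormulaCandidate],
    nitrogen_count: int | None = None,
    amide_library: Sequence[tuple[AcylSpec, float, int]] | None = None,
    tolerance_ppm: float = 100.0,
    table=DEFAULT_MASS_TABLE,
) -> list[LipidHypothesis]:
    """Combine head-group and acyl evidence into ranked whole-lipid hypotheses.

    The ester acyl comes from observed neutral losses; the amide acyl is
    searched over a free-acid library (hydroxylated and not); the head group
    from formula candidates of the head fragment.  Total deprotonated formula
    = head + amide + ester - 2 H2O - H; hypotheses are kept within
    ``tolerance_ppm`` of the precursor and ranked by |ppm|.  When an isotope
    labelling nitrogen count is supplied, hypotheses whose head group carries
    a different number of nitrogens are dropped.
    """
    # collapse the lost species (acid or ketene) to the parent free acid and
    # remember each ester's best supporting evidence for tie-breaks: mass-
    # equal acyl swaps (e.g. 3-OH-16:0 + 18:1 vs 3-OH-17:1 + 17:0) tie on
    # precursor ppm, so the higher-intensity / better-matching loss peak wins
    ester_quality: dict[AcylSpec, tuple[float, float]] = {}
    for a in loss_annotations:
        if a.kind != "neutral_loss":
            continue
        ester = AcylSpec(c=a.acyl.c, d=a.acyl.d, x=a.acyl.x, species="free_acid")
        dev_da = abs(a.ppm_error) * 1e-6 * a.acyl.mass(table)
        quality = (-a.peak.intensity, dev_da)
        ester_quality[ester] = min(ester_quality.get(ester, quality), quality)
    esters = sorted(ester_quality, key=lambda e: (e.c, e.d, e.x))
    if not esters:
        raise ValueError("no neutral-loss acyl matches to build structures from")
    if not head_candidates:
        raise ValueError("no head-group candidates to build structures from")
    if amide_library is None:
        amide_library = build_acyl_library(
            range(10, 23), range(0, 4), (0, 1), species=("free_acid",), table=table
        )
    amides = [spec for spec, _m, _n in amide_library if spec.species == "free_acid"]

    out = []
    for head in head_candidates:
        head_neutral = head_ion_to_neutral(head.formula)
        if nitrogen_count is not None and head_neutral.get("N", 0) != nitrogen_count:
            continue
        for ester in esters:
            for amide in amides:
                hyp = assemble_hypothesis(
                    head_neutral, amide, ester, precursor_mz, table
                )
                if abs(hyp.ppm_vs_precursor) <= tolerance_ppm:
                    out.append(hyp)
    out.sort(
        key=lambda h: (
            abs(h.ppm_vs_precursor),
            ester_quality[h.ester_acyl],
            sum(h.total_deprotonated_formula.values()),
        )
    )
    return out
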