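"""Synthetic multistage liver-disease cohorts.

The serum measurements behind the published HCC biomarker panels are not
publicly deposited, so this module generates staged cohorts whose per-group
marker-concentration distributions are *calibrated* to the published
operating points: for each marker we choose a log-normal location so that
the probability of exceeding the clinical cutoff equals the published
sensitivity (disease arms) or one minus the published specificity (control
arms).  Concentrations are positive and right-skewed, which makes the
log-normal the natural minimal family, and its exceedance calibration has a
closed form::

    P(X > c) = t   with  X ~ LogNormal(mu, sigma)
    mu = ln(c) - sigma * Phi^{-1}(1 - t)

The module also generates staged FPKM expression matrices with planted
secretory marker genes (for exercising the selection funnel) and two-group
survival data with exponential event times (for the Kaplan-Meier / log-rank
utilities).
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm


class Stage(str, enum.Enum):
    """Multistep hepatocarcinogenesis stage."""

    NL = "NL"        # normal liver
    CH = "CH"        # chronic hepatitis
    LC = "LC"        # liver cirrhosis
    DN = "DN"        # dysplastic nodule
    EHCC = "eHCC"    # early HCC (high-grade DN + Edmondson G1)
    AHCC = "aHCC"    # advanced HCC (Edmondson G2-G3)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


HCC_STAGES: tuple[Stage, ...] = (Stage.EHCC, Stage.AHCC)
CONTROL_STAGES: tuple[Stage, ...] = (Stage.NL, Stage.CH, Stage.LC)

_GRADES = ("G1", "G2", "G3")


@dataclass(frozen=True)
class StageLabel:
    """A stage with an optional Edmondson grade sub-tag (HCC only)."""

    base: Stage
    grade: str | None = None

    def __post_init__(self) -> None:
        if self.grade is not None:
            if self.base not in HCC_STAGES:
                raise ValueError(f"grade sub-tag only valid for HCC stages, got {self.base}")
            if self.grade not in _GRADES:
                raise ValueError(f"unknown grade {self.grade!r}")

    @property
    def is_hcc(self) -> bool:
        return self.base in HCC_STAGES

    def __str__(self) -> str:
        return self.base.value if self.grade is None else f"{self.base.value}-{self.grade}"


def parse_stage(text: str) -> StageLabel:
    """Parse ``"eHCC"`` or ``"aHCC-G2"`` style labels."""
    head, _, grade = text.partition("-")
    try:
        base = Stage(head)
    except ValueError as exc:
        raise ValueError(f"unknown stage label {text!r}") from exc
    return StageLabel(base, grade or None)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_lognormal(target_exceedance: float, cutoff: float, sigma: float) -> float:
    """Location ``mu`` such that LogNormal(mu, sigma) exceeds *cutoff* with
    probability *target_exceedance*.

    Parameters
    ----------
    target_exceedance : float in (0, 1), exclusive.
    cutoff : positive concentration (ng/mL).
    sigma : positive log-scale standard deviation.
    """
    if not 0.0 < target_exceedance < 1.0:
        raise ValueError(f"target_exceedance must lie strictly in (0, 1), got {target_exceedance}")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return float(np.log(cutoff) - sigma * norm.ppf(1.0 - target_exceedance))


@dataclass(frozen=True)
class MarkerProfile:
    """Per-stage log-normal model of one serum marker (ng/mL).

    ``stage_exceedance`` maps each stage to the probability that a subject's
    concentration exceeds ``cutoff``; the log-normal location per stage is
    derived from it at sampling time.
    """

    name: str
    cutoff: float
    stage_exceedance: Mapping[Stage, float]
    sigma: float = 1.0

    def location(self, stage: Stage) -> float:
        return calibrate_lognormal(self.stage_exceedance[stage], self.cutoff, self.sigma)

    def sample(self, stage: Stage, size: int, rng: np.random.Generator) -> np.ndarray:
        return rng.lognormal(mean=self.location(stage), sigma=self.sigma, size=size)


# Published per-marker operating points: cutoff (ng/mL), sensitivity,
# specificity — HCC (eHCC+aHCC) vs non-tumour (NL+CH+LC).
OPERATING_POINTS: dict[str, tuple[float, float, float]] = {
    "HMMR": (0.8, 0.803, 0.9186),
    "NXPH4": (7.5, 0.75, 0.7442),
    "PITX1": (2.5, 0.803, 0.6628),
    "THBS4": (90.0, 0.5758, 0.907),
    "AFP": (20.0, 0.5227, 0.8488),
}

PANEL_MARKERS: tuple[str, ...] = ("HMMR", "NXPH4", "PITX1", "THBS4")

#: The six candidates screened serologically but dropped from the final
#: panel.  No operating points were published for them; these are nominal
#: weakly-informative synthetic defaults.
DISCARDED_CANDIDATES: tuple[str, ...] = (
    "CCNB2", "CDT1", "COCH", "CSMD1", "OLFML2B", "UBE2T",
)

#: Serum test-set composition (cohort 2).
TEST_SET_COUNTS: dict[Stage, int] = {
    Stage.NL: 16, Stage.CH: 13, Stage.LC: 15, Stage.EHCC: 35, Stage.AHCC: 24,
}
#: Serum validation-set composition (cohort 3).
VALIDATION_COUNTS: dict[Stage, int] = {
    Stage.NL: 49, Stage.CH: 31, Stage.LC: 46, Stage.EHCC: 77, Stage.AHCC: 64,
}
#: Tissue transcriptome composition (high-grade DNs folded into eHCC,
#: G2+G3 into aHCC).
TISSUE_SET_COUNTS: dict[Stage, int] = {
    Stage.NL: 15, Stage.CH: 20, Stage.LC: 10, Stage.EHCC: 18, Stage.AHCC: 45,
}


def _uniform_profile(name: str, cutoff: float, sens: float, spec: float,
                     sigma: float = 1.0) -> MarkerProfile:
    fpr = 1.0 - spec
    exceed = {s: sens for s in HCC_STAGES}
    exceed.update({s: fpr for s in CONTROL_STAGES})
    exceed[Stage.DN] = sens  # dysplastic nodules treated as disease-like
    return MarkerProfile(name, cutoff, exceed, sigma)


def default_profiles(include_discarded: bool = False,
                     stage_refined_afp: bool = False,
                     sigma: float = 1.0) -> dict[str, MarkerProfile]:
    """Marker profiles calibrated to the published operating points.

    With ``stage_refined_afp`` the AFP profile instead uses the published
    per-stage positive rates (2% in NL, 33% in eHCC, 73% in aHCC), with the
    CH/LC exceedance chosen so the pooled specificity over the
    validation-design control mix still equals the published 84.88%.
    """
    profiles = {
        name: _uniform_profile(name, *point, sigma=sigma)
        for name, point in OPERATING_POINTS.items()
    }
    if stage_refined_afp:
        cutoff = OPERATING_POINTS["AFP"][0]
        # (49*0.02 + 77*x) / 126 = 1 - 0.8488  =>  x ≈ 0.2347
        profiles["AFP"] = MarkerProfile("AFP", cutoff, {
            Stage.NL: 0.02,
            Stage.CH: 0.2347, Stage.LC: 0.2347,
            Stage.DN: 1.0 / 3.0,
            Stage.EHCC: 1.0 / 3.0, Stage.AHCC: 0.73,
        }, sigma)
    if include_discarded:
        for name in DISCARDED_CANDIDATES:
            profiles[name] = _uniform_profile(name, 5.0, 0.45, 0.60, sigma=sigma)
    return profiles


@dataclass
class CohortDesign:
    """Stage composition plus marker distribution models for one cohort."""

    stage_counts: Mapping[Stage, int]
    profiles: Mapping[str, MarkerProfile] = field(default_factory=default_profiles)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for stage, n in self.stage_counts.items():
            if not isinstance(stage, Stage):
                raise TypeError(f"stage_counts keys must be Stage, got {stage!r}")
            if n < 0:
                raise ValueError(f"negative subject count for {stage}: {n}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")
        for name, prof in self.profiles.items():
            if prof.name != name:
                raise ValueError(f"profile key {name!r} does not match profile name {prof.name!r}")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.stage_counts.values()))

    def scaled(self, case_n: int, control_n: int) -> "CohortDesign":
        """Rescale to ``case_n`` HCC and ``control_n`` control subjects,
        preserving the within-arm stage proportions."""
        def split(stages: Sequence[Stage], total: int) -> dict[Stage, int]:
            weights = np.array([self.stage_counts.get(s, 0) for s in stages], dtype=float)
            if weights.sum() == 0:
                raise ValueError("design has no subjects in the requested arm")
            raw = weights / weights.sum() * total
            counts = np.floor(raw).astype(int)
            # distribute the remainder by largest fractional part
            for i in np.argsort(raw - counts)[::-1][: total - counts.sum()]:
                counts[i] += 1
            return {s: int(c) for s, c in zip(stages, counts)}

        counts = split(CONTROL_STAGES, control_n)
        counts.update(split(HCC_STAGES, case_n))
        return dataclasses.replace(self, stage_counts=counts)


def test_set_design(**kwargs) -> CohortDesign:
    return CohortDesign(dict(TEST_SET_COUNTS), **kwargs)


def validation_design(**kwargs) -> CohortDesign:
    return CohortDesign(dict(VALIDATION_COUNTS), **kwargs)


def generate_serum_cohort(design: CohortDesign,
                          seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw a serum cohort table: one row per subject, columns
    ``subject_id``, ``stage``, then one ng/mL column per marker.

    Reproducible: the same (design, seed) yields the identical table.
    Missing measurements (``missing_rate``) appear as NaN.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    markers = list(design.profiles)
    rows: list[pd.DataFrame] = []
    offset = 0
    for stage in Stage:
        n = int(design.stage_counts.get(stage, 0))
        if n == 0:
            continue
        block = {
            "subject_id": [f"P{offset + i + 1:05d}" for i in range(n)],
            "stage": [stage.value] * n,
        }
        for name in markers:
            block[name] = design.profiles[name].sample(stage, n, rng)
        rows.append(pd.DataFrame(block))
        offset += n
    if not rows:
        return pd.DataFrame(columns=["subject_id", "stage", *markers])
    cohort = pd.concat(rows, ignore_index=True)
    if design.missing_rate > 0:
        mask = rng.random((len(cohort), len(markers))) < design.missing_rate
        values = cohort[markers].to_numpy()
        values[mask] = np.nan
        cohort[markers] = values
    return cohort


# ---------------------------------------------------------------------------
# expression fixture
# ---------------------------------------------------------------------------

#: Canonical synthetic secretory leader: charged n-region (MKK), leucine
#: h-region, Ala-Ser-Ala c-region ending at the cleavage site.
SIGNAL_LEADER = "MKKLLLLLLLLASA"
_MATURE_ALPHABET = "DENQHTPYW"     # hydrophilic; never forms an h-region
_NONSIGNAL_PREFIX = "MDDEEDNQSTKG"  # acidic N-terminus, no hydrophobic core


def _mature_region(rng: np.random.Generator, length: int = 40) -> str:
    return "".join(rng.choice(list(_MATURE_ALPHABET), size=length))


@dataclass
class ExpressionFixture:
    """A staged FPKM matrix with known ground truth.

    ``matrix`` is genes x samples (FPKM); ``stages`` maps sample id to
    stage string; ``biotype``/``proteins`` annotate genes; ``signature`` is
    the external HCC gene-signature list; ``planted`` are the genes that
    satisfy all selection criteria, in decreasing planted-effect order;
    ``decoy_class`` records which single criterion each decoy violates.
    """

    matrix: pd.DataFrame
    stages: pd.Series
    biotype: dict[str, str]
    proteins: dict[str, str | None]
    signature: list[str]
    planted: list[str]
    decoy_class: dict[str, str]


DECOY_CLASSES = ("non_coding", "no_signal", "ch_lc_expressed", "not_in_signature")


def generate_expression_fixture(
    n_genes: int = 100,
    planted_markers: Sequence[str] | None = None,
    stage_counts: Mapping[Stage, int] | None = None,
    effect: float = 4.0,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 0.3,
    base_log2: float = 5.0,
    grade_step: float = 0.2,
) -> ExpressionFixture:
    """Build an FPKM matrix in which ``planted_markers`` — and only they —
    are coding, secretory (signal-peptide leader), overexpressed by
    ``effect``-fold in eHCC/aHCC relative to NL but not in CH/LC, and
    present in the signature list.  Every decoy gene violates exactly one
    of those four criteria.

    Planted effects are graded: gene *i* of the planted list receives a
    log2 offset of ``log2(effect) + grade_step * (K-1-i)``, so the list
    order is also the expected expression ranking among HCC samples.
    """
    if effect <= 1:
        raise ValueError(f"effect must exceed 1, got {effect}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if planted_markers is None:
        planted_markers = list(PANEL_MARKERS) + list(DISCARDED_CANDIDATES)
    planted = list(planted_markers)
    if len(set(planted)) != len(planted):
        raise ValueError("planted marker names must be unique")
    if stage_counts is None:
        stage_counts = dict(TISSUE_SET_COUNTS)
    if not any(stage_counts.get(s, 0) > 0 for s in HCC_STAGES):
        raise ValueError("design must include at least one HCC stage")
    if stage_counts.get(Stage.NL, 0) == 0:
        raise ValueError("design must include NL control samples")
    n_decoys = n_genes - len(planted)
    if n_decoys < 0:
        raise ValueError("n_genes smaller than the planted list")

    samples: list[str] = []
    stages: list[str] = []
    for stage in Stage:
        for i in range(int(stage_counts.get(stage, 0))):
            samples.append(f"S{len(samples) + 1:04d}")
            stages.append(stage.value)
    stage_arr = np.array(stages)
    hcc_mask = np.isin(stage_arr, [s.value for s in HCC_STAGES + (Stage.DN,)])
    chlc_mask = np.isin(stage_arr, [Stage.CH.value, Stage.LC.value])

    genes: list[str] = list(planted)
    biotype: dict[str, str] = {}
    proteins: dict[str, str | None] = {}
    decoy_class: dict[str, str] = {}
    signature: list[str] = list(planted)

    log2_effect = np.log2(effect)
    offsets = np.zeros((n_genes, len(samples)))
    k = len(planted)
    for i, gene in enumerate(planted):
        biotype[gene] = "coding"
        proteins[gene] = SIGNAL_LEADER + _mature_region(rng)
        offsets[i, hcc_mask] = log2_effect + grade_step * (k - 1 - i)

    for j in range(n_decoys):
        gene = f"DEC{j + 1:04d}"
        genes.append(gene)
        cls = DECOY_CLASSES[j % len(DECOY_CLASSES)]
        decoy_class[gene] = cls
        row = k + j
        offsets[row, hcc_mask] = log2_effect
        if cls == "non_coding":
            biotype[gene] = "non-coding"
            proteins[gene] = None
            signature.append(gene)
        elif cls == "no_signal":
            biotype[gene] = "coding"
            proteins[gene] = _NONSIGNAL_PREFIX + _mature_region(rng)
            signature.append(gene)
        elif cls == "ch_lc_expressed":
            biotype[gene] = "coding"
            proteins[gene] = SIGNAL_LEADER + _mature_region(rng)
            offsets[row, chlc_mask] = log2_effect
            signature.append(gene)
        else:  # not_in_signature
            biotype[gene] = "coding"
            proteins[gene] = SIGNAL_LEADER + _mature_region(rng)

    base = np.full(n_genes, base_log2)
    base[k:] = rng.uniform(3.0, 7.0, size=n_decoys)
    log2vals = base[:, None] + offsets + rng.normal(0.0, noise_sd, size=offsets.shape)
    log2vals = np.clip(log2vals, 0.0, None)
    fpkm = np.exp2(log2vals) - 1.0

    matrix = pd.DataFrame(fpkm, index=genes, columns=samples)
    return ExpressionFixture(
        matrix=matrix,
        stages=pd.Series(stages, index=samples, name="stage"),
        biotype=biotype,
        proteins=proteins,
        signature=signature,
        planted=planted,
        decoy_class=decoy_class,
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def generate_survival(
    n_per_group: int,
    hazard_ratio: float,
    censor_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    baseline_hazard: float = 0.1,
    groups: tuple[str, str] = ("normal", "overexpressed"),
) -> pd.DataFrame:
    """Two-group exponential survival data with independent censoring.

    The second group's hazard is ``hazard_ratio`` times the first's.
    ``censor_rate`` is the marginal probability that a subject is censored
    before its event (exactly 0 disables censoring).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError(f"censor_rate must lie in [0, 1), got {censor_rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    frames = []
    for gi, (group, hr) in enumerate(zip(groups, (1.0, hazard_ratio))):
        lam = baseline_hazard * hr
        times = rng.exponential(1.0 / lam, size=n_per_group)
        if censor_rate > 0:
            # P(C < T) = c_rate / (c_rate + lam) = censor_rate
            c_lam = lam * censor_rate / (1.0 - censor_rate)
            censor = rng.exponential(1.0 / c_lam, size=n_per_group)
            event = (times <= censor).astype(int)
            obs = np.minimum(times, censor)
        else:
            event = np.ones(n_per_group, dtype=int)
            obs = times
        frames.append(pd.DataFrame({
            "subject_id": [f"T{gi * n_per_group + i + 1:05d}" for i in range(n_per_group)],
            "time": obs,
            "event": event,
            "group": group,
        }))
    return pd.concat(frames, ignore_index=True)
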