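"""Seeded synthetic CMR-report generator with known gold labels.

Generates sectioned radiology prose (HISTORY / TECHNIQUE / FINDINGS /
MEASUREMENTS / IMPRESSION) containing asserted, negated and hedged concept
mentions, numeric measurements with units, and distractor sentences.  Because
every sentence is rendered from a template tied to the sampled gold label,
the emitted :class:`GoldAnnotation` is consistent with the text by
construction — the generator doubles as an end-to-end oracle for the
extraction pipeline.

Two error injectors emulate the failure modes seen with real reports:

* ``ambiguity_rate`` — replaces a concept sentence with a paraphrase that is
  deliberately outside the shipped lexicon (honest false negatives);
* ``misplaced_section_rate`` — plants a diagnosis mention in the HISTORY
  section of a diagnosis-negative report, or relocates a measurement into
  TECHNIQUE (wrong-section false positives).

Default prevalences and numeric distributions follow the published test-set
summaries for HCM-positive CMR reports; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .assertion import POSSIBLE
from .evaluation import GoldAnnotation, write_gold_csv
from .extraction import (
    ABSENT_NEGATED,
    NO,
    NOT_EVALUATED,
    NOT_MENTIONED,
    PRESENT,
    YES,
)
from .lexicon import CATEGORICAL_CONCEPTS, NUMERIC_CONCEPTS
from .report_model import ReportDocument, parse_report, write_corpus_jsonl


class ProfileError(ValueError):
    pass


@dataclass
class GeneratorProfile:
    """Sampling profile for the synthetic corpus.

    Probabilities of presence are conditional on a diagnosis-positive report;
    numeric distributions are (mean, sd) in canonical units, truncated to the
    plausibility bounds.
    """

    n_reports: int = 200
    seed: int = 0
    diagnosis_distribution: dict[str, float] = field(default_factory=lambda: {
        YES: 0.36, POSSIBLE: 0.04, NO: 0.35, NOT_MENTIONED: 0.25,
    })
    categorical_presence: dict[str, float] = field(default_factory=lambda: {
        "SAM": 61 / 83,
        "MITRAL_REGURGITATION": 60 / 83,
        "LV_OBSTRUCTION": 58 / 83,
        "APICAL_POUCH": 9 / 83,
        "LV_DELAYED_ENHANCEMENT": 58 / 83,
        "LA_ENLARGEMENT": 55 / 83,
        "RA_ENLARGEMENT": 18 / 83,
    })
    subtype_presence: float = 62 / 83
    subtype_distribution: dict[str, float] = field(default_factory=lambda: {
        "SIGMOID": 34 / 62, "REVERSE_CURVE": 14 / 62, "NEUTRAL": 2 / 62, "APICAL": 12 / 62,
    })
    location_distribution: dict[str, float] = field(default_factory=lambda: {
        "LVOT": 112 / 114, "MID_VENTRICULAR": 2 / 114,
    })
    numeric_presence: dict[str, float] = field(default_factory=lambda: {
        "MAX_LV_WALL_THICKNESS": 77 / 83,
        "LV_MASS": 75 / 83,
        "LV_MASS_INDEX": 71 / 83,
        "LV_EF": 77 / 83,
        "RV_EF": 75 / 83,
    })
    numeric_distributions: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            # (mean, sd, lower, upper) in canonical units
            "MAX_LV_WALL_THICKNESS": (20.9, 4.5, 3.0, 60.0),
            "LV_MASS": (198.2, 70.4, 30.0, 1000.0),
            "LV_MASS_INDEX": (97.4, 30.1, 10.0, 400.0),
            "LV_EF": (71.4, 7.9, 5.0, 95.0),
            "RV_EF": (61.0, 7.5, 5.0, 95.0),
        }
    )
    ambiguity_rate: float = 0.05
    misplaced_section_rate: float = 0.05
    max_distractors: int = 3

    def validate(self) -> None:
        def check_dist(name: str, d: dict[str, float]) -> None:
            if any(not (0.0 <= p <= 1.0) for p in d.values()):
                raise ProfileError(f"{name}: probabilities must lie in [0, 1]")
            if abs(sum(d.values()) - 1.0) > 1e-9:
                raise ProfileError(f"{name}: probabilities must sum to 1")

        if self.n_reports < 0:
            raise ProfileError("n_reports must be non-negative")
        check_dist("diagnosis_distribution", self.diagnosis_distribution)
        check_dist("subtype_distribution", self.subtype_distribution)
        check_dist("location_distribution", self.location_distribution)
        for name, p in {
            **self.categorical_presence,
            **self.numeric_presence,
            "subtype_presence": self.subtype_presence,
            "ambiguity_rate": self.ambiguity_rate,
            "misplaced_section_rate": self.misplaced_section_rate,
        }.items():
            if not (0.0 <= p <= 1.0):
                raise ProfileError(f"probability {name} out of [0, 1]: {p}")
        for cid, (_mu, sd, lo, hi) in self.numeric_distributions.items():
            if sd < 0:
                raise ProfileError(f"{cid}: sd must be non-negative")
            if lo > hi:
                raise ProfileError(f"{cid}: empty truncation interval")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorProfile":
        data = yaml.safe_load(Path(path).read_text()) or {}
        prof = cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})
        # YAML tuples arrive as lists
        prof.numeric_distributions = {
            k: tuple(v) for k, v in prof.numeric_distributions.items()  # type: ignore[misc]
        }
        prof.validate()
        return prof


@dataclass
class SyntheticRecord:
    document: ReportDocument
    gold: GoldAnnotation
    injected_errors: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Template pools.  Every template is faithful: running the extraction rules
# on it reproduces the label it encodes.

_IMPRESSION = {
    YES: [
        "Findings consistent with hypertrophic cardiomyopathy.",
        "Findings are diagnostic of hypertrophic cardiomyopathy.",
        "Hypertrophic cardiomyopathy as described above.",
    ],
    POSSIBLE: [
        "Findings possibly consistent with hypertrophic cardiomyopathy.",
        "Possible hypertrophic cardiomyopathy.",
        "Cannot exclude hypertrophic cardiomyopathy.",
    ],
    NO: [
        "There is no evidence for hypertrophic cardiomyopathy.",
        "No evidence of hypertrophic cardiomyopathy.",
        "The findings are not consistent with hypertrophic cardiomyopathy.",
    ],
    NOT_MENTIONED: [
        "Normal cardiac MRI examination.",
        "Stable examination compared with prior.",
    ],
}

_SUBTYPE_SENT = {
    "SIGMOID": "Septal contour is consistent with the sigmoid morphologic subtype.",
    "REVERSE_CURVE": "Septal morphology is of the reverse curve subtype.",
    "NEUTRAL": "Septal contour is of the neutral subtype.",
    "APICAL": "The pattern of hypertrophy is of the apical morphologic subtype.",
}

_CATEGORICAL_SENT = {
    "SAM": {
        PRESENT: [
            "Systolic anterior motion of the mitral valve is present.",
            "There is systolic anterior motion of the mitral valve.",
        ],
        ABSENT_NEGATED: [
            "No systolic anterior motion of the mitral valve.",
            "Systolic anterior motion is not seen.",
        ],
    },
    "MITRAL_REGURGITATION": {
        PRESENT: [
            "Mitral regurgitation is present.",
            "There is moderate mitral regurgitation.",
        ],
        ABSENT_NEGATED: [
            "No mitral regurgitation seen.",
            "There is no mitral regurgitation.",
        ],
    },
    "APICAL_POUCH": {
        PRESENT: [
            "A small apical pouch is noted.",
            "There is an apical pouch.",
        ],
        ABSENT_NEGATED: [
            "No evidence of apical pouch.",
            "No apical pouch is identified.",
        ],
    },
    "LV_DELAYED_ENHANCEMENT": {
        PRESENT: [
            "Delayed myocardial enhancement within the left ventricular apex.",
            "There is delayed myocardial enhancement of the septum.",
        ],
        ABSENT_NEGATED: [
            "Delayed myocardial enhancement is not present.",
            "No delayed enhancement is seen.",
        ],
    },
    "LA_ENLARGEMENT": {
        PRESENT: [
            "Enlarged left atrium.",
            "The left atrium is moderately enlarged.",
        ],
        ABSENT_NEGATED: [
            "No significant left atrial enlargement.",
            "No left atrial enlargement.",
        ],
    },
    "RA_ENLARGEMENT": {
        PRESENT: [
            "Right atrial enlargement.",
            "The right atrium is mildly enlarged.",
        ],
        ABSENT_NEGATED: [
            "No significant right atrial enlargement.",
            "No right atrial enlargement.",
        ],
    },
}

# obstruction sentence also carries the location when present
_OBSTRUCTION_SENT = {
    "LVOT": [
        "There is turbulent flow in the left ventricular outflow tract.",
        "Flow acceleration is noted in the left ventricular outflow tract.",
    ],
    "MID_VENTRICULAR": [
        "Turbulent flow is present in the mid chamber.",
        "There is turbulent flow at the mid-ventricular level.",
    ],
    ABSENT_NEGATED: [
        "No turbulence is seen in the left ventricular outflow tract.",
        "No turbulence is seen in the LV outflow tract.",
    ],
}

_NUMERIC_SENT = {
    "MAX_LV_WALL_THICKNESS": [
        "The maximal thickness of the myocardium measured in diastole is {v} mm.",
        "Maximal wall thickness is {v} mm.",
    ],
    "LV_MASS": ["LV End Diastolic Mass = {v} g."],
    "LV_MASS_INDEX": ["LV End Diastolic Mass Index = {v} g/m2."],
    "LV_EF": [
        "LV Ejection Fraction: {v}%.",
        "The left ventricular ejection fraction is {v}%.",
    ],
    "RV_EF": ["RV Ejection Fraction: {v}%."],
}

_HISTORY = [
    "Referred for further evaluation.",
    "Follow-up examination.",
    "Evaluation of cardiac function.",
]

_TECHNIQUE = [
    "Cardiac MRI was performed with and without contrast.",
    "Standard imaging protocol was performed.",
]

_DISTRACTORS = [
    "The lungs are clear.",
    "There is no pericardial effusion.",
    "The aortic valve is trileaflet.",
    "No pleural effusion is seen.",
    "The thoracic aorta is normal in caliber.",
]

#: paraphrases deliberately outside the shipped lexicon (ambiguity injector)
PARAPHRASE_POOL = {
    "HCM_DIAGNOSIS": "Marked asymmetric septal thickening as described above.",
    "SAM": "The anterior mitral leaflet drifts toward the septum in systole.",
    "LV_OBSTRUCTION": "A cavity gradient is appreciated.",
    "LA_ENLARGEMENT": "The left atrium appears capacious.",
    "LV_DELAYED_ENHANCEMENT": "Patchy contrast retention is noted in the septum.",
}

_MISPLACED_HISTORY = "Known hypertrophic cardiomyopathy, referred for imaging."


def _choice(rng: np.random.Generator, options: list[str]) -> str:
    return options[int(rng.integers(len(options)))]


def _sample_label(rng: np.random.Generator, dist: dict[str, float]) -> str:
    labels = list(dist.keys())
    probs = np.asarray([dist[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    return labels[int(rng.choice(len(labels), p=probs))]


def _sample_truncnorm_int(rng: np.random.Generator, mu: float, sd: float, lo: float, hi: float) -> int:
    for _ in range(1000):
        x = rng.normal(mu, sd)
        if lo <= x <= hi:
            return int(round(x))
    return int(round(min(max(mu, lo), hi)))


def generate_report(profile: GeneratorProfile, index: int) -> SyntheticRecord:
    """Generate one report; byte-identical for identical (profile, index)."""
    profile.validate()
    rng = np.random.default_rng([profile.seed, index])
    report_id = f"synth-{index:05d}"
    gold = GoldAnnotation(report_id=report_id, diagnosis=_sample_label(rng, profile.diagnosis_distribution))
    errors: list[dict] = []

    positive = gold.diagnosis in (YES, POSSIBLE)
    findings: list[str] = []   # (concept_id, sentence) pairs flattened below
    tagged: list[tuple[str, str]] = []
    measurements: list[str] = []

    if positive:
        # morphologic subtype
        if rng.random() < profile.subtype_presence:
            gold.subtype = _sample_label(rng, profile.subtype_distribution)
            tagged.append(("HCM_SUBTYPE", _SUBTYPE_SENT[gold.subtype]))
        else:
            gold.subtype = NOT_MENTIONED
        # obstruction with location
        if rng.random() < profile.categorical_presence["LV_OBSTRUCTION"]:
            gold.categoricals["LV_OBSTRUCTION"] = PRESENT
            gold.obstruction_location = _sample_label(rng, profile.location_distribution)
            tagged.append(("LV_OBSTRUCTION", _choice(rng, _OBSTRUCTION_SENT[gold.obstruction_location])))
        else:
            gold.categoricals["LV_OBSTRUCTION"] = ABSENT_NEGATED
            gold.obstruction_location = NOT_MENTIONED
            tagged.append(("LV_OBSTRUCTION", _choice(rng, _OBSTRUCTION_SENT[ABSENT_NEGATED])))
        # remaining binary concepts
        for cid in CATEGORICAL_CONCEPTS:
            if cid == "LV_OBSTRUCTION":
                continue
            status = PRESENT if rng.random() < profile.categorical_presence[cid] else ABSENT_NEGATED
            gold.categoricals[cid] = status
            tagged.append((cid, _choice(rng, _CATEGORICAL_SENT[cid][status])))
        # numeric measurements
        for cid in NUMERIC_CONCEPTS:
            if rng.random() < profile.numeric_presence[cid]:
                mu, sd, lo, hi = profile.numeric_distributions[cid]
                v = _sample_truncnorm_int(rng, mu, sd, lo, hi)
                gold.numerics[cid] = float(v)
                measurements.append(_choice(rng, _NUMERIC_SENT[cid]).format(v=v))
            else:
                gold.numerics[cid] = None
    else:
        gold.subtype = NOT_EVALUATED
        gold.obstruction_location = NOT_EVALUATED
        for cid in CATEGORICAL_CONCEPTS:
            gold.categoricals[cid] = NOT_EVALUATED
        for cid in NUMERIC_CONCEPTS:
            gold.numerics[cid] = NOT_EVALUATED
        # ventricular function is still measured on non-HCM studies
        for cid in ("LV_EF", "RV_EF"):
            if rng.random() < profile.numeric_presence[cid]:
                mu, sd, lo, hi = profile.numeric_distributions[cid]
                v = _sample_truncnorm_int(rng, mu, sd, lo, hi)
                measurements.append(_choice(rng, _NUMERIC_SENT[cid]).format(v=v))

    # ambiguity injection: swap one concept sentence for an unlexiconed paraphrase
    impression = _choice(rng, _IMPRESSION[gold.diagnosis])
    if rng.random() < profile.ambiguity_rate:
        candidates = [
            cid for cid, _ in tagged
            if cid in PARAPHRASE_POOL and gold.categoricals.get(cid) == PRESENT
        ]
        if gold.diagnosis == YES:
            candidates.append("HCM_DIAGNOSIS")
        if candidates:
            victim = candidates[int(rng.integers(len(candidates)))]
            if victim == "HCM_DIAGNOSIS":
                impression = PARAPHRASE_POOL[victim]
            else:
                tagged = [
                    (cid, PARAPHRASE_POOL[cid] if cid == victim else s) for cid, s in tagged
                ]
            errors.append({"type": "paraphrase", "location": victim})

    history = _choice(rng, _HISTORY)
    technique = _choice(rng, _TECHNIQUE)

    # wrong-section injection
    if rng.random() < profile.misplaced_section_rate:
        if not positive:
            history = _MISPLACED_HISTORY
            errors.append({"type": "misplaced_section", "location": "HISTORY"})
        elif measurements:
            k = int(rng.integers(len(measurements)))
            technique = technique + " " + measurements.pop(k)
            errors.append({"type": "misplaced_section", "location": "TECHNIQUE"})

    findings = [s for _, s in tagged]
    n_distract = int(rng.integers(1, profile.max_distractors + 1))
    for _ in range(n_distract):
        pos = int(rng.integers(len(findings) + 1))
        findings.insert(pos, _choice(rng, _DISTRACTORS))

    lines = [
        "HISTORY: " + history,
        "TECHNIQUE: " + technique,
        "FINDINGS: " + " ".join(findings),
    ]
    if measurements:
        lines.append("MEASUREMENTS: " + " ".join(measurements))
    lines.append("IMPRESSION: " + impression)
    text = "\n".join(lines) + "\n"

    doc = parse_report(report_id, text, patient_id=f"pt-{index:05d}")
    return SyntheticRecord(document=doc, gold=gold, injected_errors=errors)


def generate_corpus(
    profile: GeneratorProfile, out_dir: str | Path | None = None
) -> list[SyntheticRecord]:
    """Generate ``profile.n_reports`` records; optionally write the JSONL
    corpus and gold CSV under ``out_dir``."""
    profile.validate()
    records = [generate_report(profile, i) for i in range(profile.n_reports)]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_corpus_jsonl([r.document for r in records], out_dir / "corpus.jsonl")
        write_gold_csv([r.gold for r in records], out_dir / "gold.csv")
    return records
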