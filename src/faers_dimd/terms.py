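"""Controlled vocabulary used across the pipeline.

MedDRA preferred terms (PTs) are matched after normalization: uppercase with
internal whitespace removed, e.g. "Tardive dyskinesia" -> "TARDIVEDYSKINESIA".
The drug-induced movement disorder (DIMD) case definition is the 28-PT set
below; a report is a case if at least one of its reaction PTs normalizes into
this set.
"""

from __future__ import annotations

# Display-form PTs defining the DIMD event class (28 terms).  The normalized
# forms of these strings are the canonical case-definition set.
DIMD_PT_DISPLAY: tuple[str, ...] = (
    "Muscle twitching",
    "Tic",
    "Tardive dyskinesia",
    "Drooling",
    "Dyskinesia",
    "Choreoathetosis",
    "Movement disorder",
    "Grimacing",
    "Motor dysfunction",
    "Extrapyramidal disorder",
    "Dyskinesia neonatal",
    "Chorea",
    "Buccoglossal syndrome",
    "Athetosis",
    "Ballismus",
    "Dyskinesia oesophageal",
    "Respiratory dyskinesia",
    "Oculogyric crisis",
    "Dopamine dysregulation syndrome",
    "Protrusion tongue",
    "Rabbit syndrome",
    "Pharyngeal dyskinesia",
    "Abnormal involuntary movement scale",
    "Chronic tic disorder",
    "Secondary tic",
    "Provisional tic disorder",
    "Oculogyration",
    "Reduced dexterity",
)


def normalize_pt(raw: str) -> str:
    """Normalize a MedDRA PT: uppercase, all internal whitespace removed."""
    return "".join(str(raw).split()).upper()


DIMD_PTS: frozenset[str] = frozenset(normalize_pt(t) for t in DIMD_PT_DISPLAY)

# Background (non-DIMD) reaction PTs used by the synthetic generator.  None of
# these normalize into the DIMD set.
BACKGROUND_PT_DISPLAY: tuple[str, ...] = (
    "Nausea",
    "Headache",
    "Fatigue",
    "Rash",
    "Dizziness",
    "Vomiting",
    "Diarrhoea",
    "Pyrexia",
    "Pruritus",
    "Insomnia",
    "Anxiety",
    "Dyspnoea",
    "Arthralgia",
    "Oedema peripheral",
    "Abdominal pain",
    "Constipation",
    "Hypotension",
    "Weight decreased",
)

# FAERS patient-outcome codes (OUTC.outc_cod).
OUTCOME_CODES: tuple[str, ...] = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

# FAERS reporter-occupation codes (DEMO.occp_cod).
OCCUPATION_CODES: tuple[str, ...] = ("MD", "PH", "OT", "CN", "LW", "RN", "HP")

# FAERS drug role codes (DRUG.role_cod): prime suspect, secondary suspect,
# concomitant, interaction.
ROLE_CODES: tuple[str, ...] = ("PS", "SS", "C", "I")

COUNTRY_CODES: tuple[str, ...] = (
    "US", "GB", "CA", "FR", "DE", "JP", "IT", "NL", "BR", "CN", "AU", "ES",
)
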