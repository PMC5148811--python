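"""Column contracts and the MDASI item inventory.

All tables exchanged between pipeline stages (and serialized as CSV) are
plain pandas DataFrames following the column contracts below.  The 19
MDASI items are the 13 core symptom-severity items plus the 6 items
rating interference with daily life, each self-scored 0-10.
"""

from __future__ import annotations

# 13 symptom-severity items, in fixed order.
MDASI_SYMPTOMS = (
    "pain",
    "fatigue",
    "nausea",
    "disturbed_sleep",
    "distress",
    "shortness_of_breath",
    "remembering",
    "lack_of_appetite",
    "drowsiness",
    "dry_mouth",
    "sadness",
    "vomiting",
    "numbness_tingling",
)

# 6 daily-life interference items, in fixed order.
MDASI_INTERFERENCE = (
    "general_activity",
    "mood",
    "work",
    "relations_with_others",
    "walking",
    "enjoyment_of_life",
)

MDASI_ITEMS = MDASI_SYMPTOMS + MDASI_INTERFERENCE

#: daily.csv columns holding MDASI scores.
MDASI_COLUMNS = tuple(f"mdasi_{item}" for item in MDASI_ITEMS)

#: Fixed feature order of the discriminant model: 13 symptoms, 6
#: interference items, body-weight change, dichotomy index.
FEATURE_NAMES = MDASI_ITEMS + ("weight_change", "io")

EPOCHS_COLUMNS = ("patient_id", "timestamp", "activity_count", "in_bed", "observed")
DAILY_COLUMNS = ("patient_id", "date", "weight_kg") + MDASI_COLUMNS + ("hospitalized",)
EVENTS_COLUMNS = ("patient_id", "admission_date", "discharge_date", "planned")
COURSES_COLUMNS = ("patient_id", "start_date", "end_date", "location")
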