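"""Numeric encoding and free-text variable extraction.

Shows the four encoders (ordinal, binary, one-hot with missingness
indicator, frequency ranking) and the extraction of structured presence
variables from free-text clinical notes.
"""

import pandas as pd

from hedkit.core import MISSING, HealthTable
from hedkit.transform import (
    FreeTextSpec,
    assert_all_numeric,
    encode_binary,
    encode_by_frequency,
    encode_onehot,
    encode_ordinal,
    extract_freetext,
)

frame = pd.DataFrame(
    {
        "n_stage": ["N0", "N2", "N1", MISSING],
        "smoker": ["yes", "no", "no", "yes"],
        "marital": ["married", "single", MISSING, "married"],
        "kras": ["WT", "WT", "Het", "Hom"],
        "notes": ["mother had breast cancer", "father had lung cancer",
                  MISSING, "mother had breast cancer"],
    },
    index=pd.Index(["p1", "p2", "p3", "p4"], name="id"), dtype=object,
)
table = HealthTable(frame, id_name="id")

table, mapping = encode_ordinal(table, "n_stage", ["N0", "N1", "N2"])
print("ordinal n_stage -> codes:", list(table.values("n_stage")))

table = encode_binary(table, "smoker", positive_label="yes")
print("binary smoker -> codes:", list(table.values("smoker")))

table = encode_onehot(table, "marital")
print("one-hot marital ->",
      [v for v in table.variables if v.startswith("marital_")])
print("  marital_NA marks the missing record:",
      list(table.values("marital_NA")))

table, freq_map = encode_by_frequency(table, "kras")
print("frequency-encoded kras (most common status = 0):",
      freq_map.decode("kras"))

spec = FreeTextSpec(variable="notes", min_record_frequency=2, ngram_length=2,
                    skip_window=1)
table = extract_freetext(table, spec)
table.drop_variable("notes")
print("terms extracted from notes:",
      [v for v in table.variables if v.startswith("notes_")])

offenders = assert_all_numeric(table)
print("all-numeric assertion:", "pass" if not offenders else offenders)
print("\nlabel-to-code mappings are kept in a reference table:")
print(mapping.to_frame().to_string(index=False))
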