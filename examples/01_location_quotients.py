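"""Location quotients and concentration sets on a tiny two-region table.

The location quotient LQ_ir compares a surname's share of a region's
population with its share of the total population; LQ > 1 means the surname
concentrates there.
"""

import pandas as pd

from surnamespace import SurnameCountTable, concentration_sets, location_quotients

table = SurnameCountTable(
    pd.DataFrame(
        {
            "surname": ["Vlček", "Vlček", "Wolf", "Wolf", "Novák", "Novák"],
            "region": ["west", "east", "west", "east", "west", "east"],
            "count": [80, 20, 70, 30, 50, 50],
        }
    )
)

lq = location_quotients(table)
print(lq.to_dataframe().to_string(index=False))

conc = concentration_sets(lq)
for surname in table.surnames:
    print(f"{surname}: concentrates in {sorted(conc.concentration_set(surname)) or 'no region'}")

# Vlček and Wolf both have LQ > 1 only in the west (their bearers are
# over-represented there relative to the whole population); Novák's 50/50
# split matches the overall population closely enough that it concentrates
# only weakly or not at all.
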