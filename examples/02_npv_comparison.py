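"""Compare the expected NPV of establishing rubber vs oil palm.

At the 2012 farm-gate reference prices (1100 USD/t dry rubber, 90 USD/t
fresh fruit bunches) a fully efficient household weighing up a bare
field finds rubber the better investment at every planning horizon —
the driver of the landscape-wide rubber transition under constant
prices.
"""

from smallholder import OIL_PALM, RUBBER, default_oil_palm, default_rubber
from smallholder.economy import REPLANT, expected_npv_per_cell

crops = {OIL_PALM: default_oil_palm(), RUBBER: default_rubber()}
prices = {OIL_PALM: 90.0, RUBBER: 1100.0}
efficient = {OIL_PALM: 0.0, RUBBER: 0.0}

print("horizon  NPV/ha rubber  NPV/ha oil palm")
for horizon in (1, 5, 10, 15, 20):
    npv = {
        crop: 4 * expected_npv_per_cell(
            crops, crop, 0, REPLANT, prices, efficient, horizon, 0.10
        )
        for crop in (RUBBER, OIL_PALM)
    }
    print(f"{horizon:7d}  {npv[RUBBER]:13.0f}  {npv[OIL_PALM]:15.0f}")
# Both NPVs are negative at short horizons (establishment costs dominate
# before stands mature), but rubber is always the less costly/more
# profitable choice, so replacement decisions systematically pick rubber.
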