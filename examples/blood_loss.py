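"""Estimate intraoperative blood loss from suction and gauze records.

Net suction output (total minus irrigation fluid) plus the gravimetric
gauze estimate at 0.56 mL of blood per gram of weight gain.
"""

from paramuscle import estimate_blood_loss

suction_total = 300.0   # mL collected in the suction canister
irrigation = 250.0      # mL of irrigation fluid used
gauze_gain = 18.0       # g of weight gained by blood-saturated gauzes

loss = estimate_blood_loss(suction_total, irrigation, gauze_gain)
print(f"net suction : {suction_total - irrigation:.1f} mL")
print(f"gauze       : 0.56 x {gauze_gain:.0f} g = {0.56 * gauze_gain:.2f} mL")
print(f"total loss  : {loss:.2f} mL")
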