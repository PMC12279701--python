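"""Extrapolate the reference country's assistive-technology workforce.

Pools the staffing tables of three Swedish healthcare regions (8.9% of the
national population) and scales them to the national population, per product
domain and workforce class.  Writes the national estimate table to
results/reference_workforce.csv.

Finding: the three regions' 470.5 FTE extrapolate to ~5,300 FTE nationally
(502 FTE per million population), of which ~4,115 FTE are clinical and
non-clinical staff (390 FTEPM); mobility & self-care is by far the largest
domain (~2,800 FTE) and cognition & communication the smallest (~175 FTE).
"""

from pathlib import Path

from atworkforce import refdata
from atworkforce.io import national_estimate_frame
from atworkforce.workforce import extrapolate_national, extrapolate_prescribers

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    region = refdata.regional_workforce()
    estimate = extrapolate_national(region, refdata.SWEDEN_POPULATION)
    frame = national_estimate_frame(estimate)

    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "reference_workforce.csv", index=False)

    print("National workforce extrapolated from three regions "
          f"(P_R = {region.population:,}, P_S = {refdata.SWEDEN_POPULATION:,}):\n")
    print(frame.to_string(index=False))

    prescribers = extrapolate_prescribers(
        refdata.prescriber_count(), refdata.SWEDEN_POPULATION, rounded=True
    )
    print(f"\nNational prescriber head count (cognition/communication + "
          f"mobility/self-care): ~{prescribers:,.0f}")
    print(f"\nWritten to {OUT / 'reference_workforce.csv'}")


if __name__ == "__main__":
    main()
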