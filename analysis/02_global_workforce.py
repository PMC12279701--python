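"""Scale the reference workforce to global assistive-product needs.

Runs the reference-mode pipeline: the national workforce per domain is
multiplied by the ratio of global to national need (W_G = W_S * N_G / N_S),
with opposite-bound CI propagation, the +/-50% productivity sensitivity
analysis, and the prescriber extrapolation.  Writes all output tables, the
results JSON and a markdown report under results/global/.

Finding: achieving a high level of access globally requires ~4.4 (95% CI
2.9-6.9) million FTE in total, ~3.4 (2.3-5.5) million clinical/non-clinical
FTE, and ~16 (12-21) million prescribers; under +/-50% productivity the
total band is 2.2-6.6 million FTE.
"""

from pathlib import Path

from atworkforce.pipeline import RunConfig, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "global"


def main() -> None:
    result = run_pipeline(RunConfig(mode="reference", seed=0, output_dir=str(OUT)))
    req = result.results["workforce_requirement"]["all_domains"]
    p = result.results["prescribers_global"]
    print("Required global workforce for a high level of access:\n")
    print(f"  total:    {req['total_mfte']:.2f} M FTE "
          f"(95% CI {req['total_ci_mfte'][0]:.2f}-{req['total_ci_mfte'][1]:.2f}), "
          f"{req['total_ftepm']:.0f} FTE per million population")
    print(f"  clinical: {req['clinical_mfte']:.2f} M FTE "
          f"(95% CI {req['clinical_ci_mfte'][0]:.2f}-{req['clinical_ci_mfte'][1]:.2f})")
    lo, hi = req["sensitivity_total_mfte"]
    print(f"  +/-50% productivity band (total): {lo:.1f}-{hi:.1f} M FTE")
    print(f"  prescribers: {p['point'] / 1e6:.1f} M "
          f"(95% CI {p['ci_low'] / 1e6:.1f}-{p['ci_high'] / 1e6:.1f})")
    print(f"\nTables, results.json and report.md written to {OUT}")


if __name__ == "__main__":
    main()
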