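"""Transmural cable at sinus pacing: CV calibration, wavelength, EAT/EDT.

Calibrates the layered endo/M/epi cable to the sinus conduction
velocities (67.4 cm/s WT, 64.7 cm/s mutant), paces at BCL 600 ms and
reports mid-cable APD90, conduction wavelength and the activation /
repolarization spread proxies.  Writes results/cable/.
"""

from shortqt.pipeline import RunConfig, run_experiment


def main() -> None:
    cfg = RunConfig(experiment="sinus-cable", name="transmural-cable",
                    out_dir="results/cable")
    bundle = run_experiment(cfg)
    df = bundle["cable"].round(2)
    print("Transmural cable at BCL 600 ms (calibrated conduction):")
    print(df.to_string(index=False))
    wl = df.set_index("condition")["wavelength_cm"]
    red = 100.0 * (1.0 - wl["s140g"] / wl["wt"])
    print(f"\nThe mutant shortens the conduction wavelength by "
          f"{red:.0f}% while the activation\nspread (QRS proxy) is nearly "
          "unchanged - repolarization, not conduction, carries\nthe "
          "phenotype.")


if __name__ == "__main__":
    main()
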