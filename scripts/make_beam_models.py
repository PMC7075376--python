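"""Regenerate the packaged beam-model YAML files from the analytic model."""

from pathlib import Path

from gridfire.dose import BeamModel

DATA = Path(__file__).resolve().parents[1] / "src" / "gridfire" / "data"

if __name__ == "__main__":
    DATA.mkdir(parents=True, exist_ok=True)
    for energy in ("6MV", "18MV"):
        model = BeamModel.analytic(energy)
        out = DATA / f"{energy}.yaml"
        model.to_yaml(out)
        print(f"wrote {out}")
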