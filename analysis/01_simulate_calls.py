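"""Synthesize the call corpus: telephone-band audio + Audacity labels + metadata.

Generates six synthetic helpline calls (three female, three male callers)
with per-segment distress ratings via source-filter synthesis, writes them
under results/run/audio/, and prints the corpus summary.  Every downstream
script reads from the same run directory.
"""

from _common import config

from vocaldistress.pipeline import run_stage

if __name__ == "__main__":
    out = run_stage("simulate", config())
    wavs = sorted((out / "audio").glob("*.wav"))
    print(f"wrote {len(wavs)} calls to {out / 'audio'}")
    for w in wavs:
        print(f"  {w.name}")
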