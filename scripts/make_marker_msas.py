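"""Regenerate the packaged synthetic marker alignments.

The three marker families (TerL, MCP, portal) shipped under
src/phagering/data/ are synthetic: each is a family of diverged copies of a
random ancestral protein, built deterministically from a fixed seed.  They
stand in for curated marker alignments so that the profile search and the
community generator are self-contained; they carry no biological sequence.

Run from the repository root:  python scripts/make_marker_msas.py
"""

from pathlib import Path

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"

FAMILIES = {  # name -> (category, length, n_seqs, substitution rate)
    "terl_synthetic": ("TerL", 140, 24, 0.12),
    "mcp_synthetic": ("MCP", 125, 24, 0.12),
    "portal_synthetic": ("portal", 130, 24, 0.12),
}
SEED = 20210331


def make_family(rng, length, n, rate):
    aas = np.array(list(AA))
    anc = rng.integers(0, 20, size=length)
    seqs = []
    for _ in range(n):
        s = anc.copy()
        mut = rng.random(length) < rate
        s[mut] = rng.integers(0, 20, size=int(mut.sum()))
        seqs.append("".join(aas[s]))
    return seqs


def main():
    out_dir = Path(__file__).resolve().parents[1] / "src" / "phagering" / "data"
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    for name, (cat, length, n, rate) in FAMILIES.items():
        seqs = make_family(rng, length, n, rate)
        path = out_dir / f"{name}.afa"
        with open(path, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">{name}_{i:02d} category={cat} synthetic\n{s}\n")
        print(f"wrote {path} ({n} x {length})")


if __name__ == "__main__":
    main()
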