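#!/usr/bin/env python
"""Extract the conserved signature windows and build the reduced phylogeny.

Scans each protein for the 44-residue motif planted by the simulator,
writes the windows plus 50-residue flanks, builds the neighbor-joining
tree on window+flank p-distances with 500 bootstrap replicates, and
reports the tree's Fitch parsimony length. Writes results/phylogeny/.
"""

from dataclasses import asdict
from pathlib import Path

from ugtevol.io import read_fasta, write_fasta, write_tsv
from ugtevol.motif import build_profile, scan_pspg
from ugtevol.phylogeny import bootstrap, fitch_score, nj_tree, p_distance

FAMILY = Path(__file__).resolve().parent.parent / "results" / "family"
OUT = Path(__file__).resolve().parent.parent / "results" / "phylogeny"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    proteins = read_fasta(FAMILY / "proteins.fasta")
    motif = (FAMILY / "motif.txt").read_text().strip()
    profile = build_profile([motif])

    hits = []
    windows = {}
    for pid, seq in proteins.items():
        (hit,) = scan_pspg(pid, seq, profile, flank_len=50)
        hits.append(hit)
        windows[pid] = hit.flank_up + hit.window + hit.flank_down
    write_tsv(
        OUT / "motif_hits.tsv",
        [asdict(h) for h in hits],
        ["protein_id", "start", "end", "score", "window", "flank_up", "flank_down"],
    )
    write_fasta(OUT / "motif_windows.fasta", windows)
    print(f"motif found in {len(hits)}/{len(proteins)} proteins at positions "
          f"{sorted({(h.start, h.end) for h in hits})}")

    dm = p_distance(windows)
    (OUT / "distances.phy").write_text(dm.to_phylip())
    tree = nj_tree(dm)
    tree.supports = bootstrap(windows, n_reps=500, seed=SEED)
    (OUT / "tree.nwk").write_text(tree.newick() + "\n")
    print(f"NJ tree: {tree.newick()}")
    for split, support in sorted(tree.supports.items(), key=lambda kv: -kv[1]):
        print(f"  split {sorted(split)}: {support:.0f}% bootstrap support")

    score = fitch_score(tree, windows)
    print(f"Fitch parsimony length of the NJ topology: {score} changes "
          f"over {len(next(iter(windows.values())))} columns")


if __name__ == "__main__":
    main()
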