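"""Generate the two study fixtures: strict cospeciation vs three host switches.

Both scenarios share one Yule host tree realisation (8 hosts), one GTR+G+I
model (alpha = 0.5, p_inv = 0.1, transition bias 4) and one alignment length
(2,000 nt); they differ only in the number of host-switch (SPR) events
applied to the virus tree.  Everything downstream reads these bundles.
"""

from pathlib import Path

from cophylo.simulate import (
    COSPECIATION_8TAXA,
    FIXTURE_LENGTH,
    FIXTURE_MODEL,
    SWITCH3_8TAXA,
    make_fixture,
)
from cophylo.tree import map_and_prune, rf_distance, write_newick

RESULTS = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    for name, scenario in (("cospeciation", COSPECIATION_8TAXA),
                           ("switch3", SWITCH3_8TAXA)):
        outdir = RESULTS / name
        outdir.mkdir(parents=True, exist_ok=True)
        bundle = make_fixture(scenario, FIXTURE_MODEL, FIXTURE_LENGTH, outdir)
        pruned = map_and_prune(bundle.virus_tree, bundle.association)
        rf = rf_distance(pruned, bundle.host_tree)
        print(f"[{name}] n_switches={scenario.n_switches} "
              f"RF(virus, host) = {rf} "
              f"(0 means the virus exactly tracks the host phylogeny)")
        print(f"  host:  {write_newick(bundle.host_tree, 4)}")
        print(f"  virus: {write_newick(bundle.virus_tree, 4)}")
        print(f"  wrote {outdir}")


if __name__ == "__main__":
    main()
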