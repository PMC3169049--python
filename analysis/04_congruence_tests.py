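"""The three host-virus congruence tests on both fixtures.

Expected pattern: under strict cospeciation the SH test is null (2dlnL = 0,
p = 1), nearly all posterior topologies match the host tree, and no random
topology beats the posterior.  With three host switches the SH test rejects
decisively, no posterior topology matches, and only a small fraction of
random topologies come closer to the host tree than the posterior does —
residual similarity from the unswitched part of the history.
"""

from pathlib import Path

from cophylo.congruence import CongruenceConfig, run_congruence_suite
from cophylo.io import read_association, read_fasta, read_nexus_trees
from cophylo.mcmc import MCMCConfig
from cophylo.tree import parse_newick

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "congruence"
    out.mkdir(parents=True, exist_ok=True)
    for name, seed in (("cospeciation", 21), ("switch3", 22)):
        fdir = ROOT / "fixtures" / name
        aln = read_fasta(fdir / "alignment.fasta")
        host = parse_newick((fdir / "host.nwk").read_text())
        assoc = read_association(fdir / "association.tsv")
        posterior_path = ROOT / "posterior" / f"{name}.t"
        external = None
        if posterior_path.exists():  # reuse the chains from step 03
            external = read_nexus_trees(posterior_path)
            external.burnin_applied = True
        config = CongruenceConfig(
            candidates=("GTR+G+I",), n_rell=1000, n_random=10_000,
            summary="mean", seed=seed,
            mcmc=MCMCConfig(generations=50_000, sample_interval=100,
                            burnin_fraction=0.25, seed=seed + 100),
            posterior=external,
        )
        if external is not None:
            config.posterior.burnin_applied = True
        report = run_congruence_suite(aln, host, assoc, config)
        (out / f"{name}_report.txt").write_text(report.to_text())
        print(f"[{name}]")
        for line in report.summary_text().splitlines():
            print(f"  {line}")


if __name__ == "__main__":
    main()
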