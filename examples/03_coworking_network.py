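"""Build a collector coworking network under both weighting schemes.

A two-person record contributes the maximum tie weight of 1 under the
hyperbolic rule; a trio spreads 3/2 over its three pairs (1/2 each); a
single-collector record creates a node but no tie.
"""

from colnet import Team, build_cwn, individualists
from colnet.network_analytics import team_size_stats

teams = [
    Team("r0", ("irwin,hs", "ratter,ja")),
    Team("r1", ("irwin,hs", "ratter,ja")),
    Team("r2", ("proenca,ceb", "faria,jeq", "mendes,vc")),
    Team("r3", ("staggemeier,vg",)),
]

for scheme in ("hyperbolic", "full_count"):
    cwn = build_cwn(teams, scheme=scheme)
    weights = {(u, v): w for u, v, w in cwn.graph.edges(data="weight")}
    print(f"{scheme:11} weights: {weights}")

cwn = build_cwn(teams)
print("individualists (degree 0):", individualists(cwn))
stats = team_size_stats(teams)
print(f"team sizes {stats.histogram}, mean {stats.mean:.2f}")
# hyperbolic w(irwin,ratter)=2.0: two shared two-person records, 1 each.
# The trio's pairs get 1/(3-1)=0.5 each; the solo collector stays isolated.
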