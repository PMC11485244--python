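"""Synthetic stand-in chains for the heteromeric ANXA11/TDP-43 filament system.

These sequences are SYNTHETIC: they are not the UniProt entries for ANXA11
(P50995) or TDP-43 (Q13148).  They were constructed once, deterministically,
to satisfy the published constraints on the regions that matter for this
package, so that every analysis can be exercised and demonstrated without
external downloads:

ANXA11-like chain (505 residues, ~56.0 kDa full length)
  * proline-rich N-terminal low-complexity region, except that the span
    I37-M70 is proline-free and P71 is the single proline of the ordered
    segment L39-Y74;
  * named residues fixed at their published positions: I37, L39, T44, Q51,
    L54, S55, N60, T64, G66, N69, M70, P71, Y74;
  * residues 56-66 (GNSSNMSATWG) match the 11-residue density-derived
    motif G[NMQ]X[SA][EDRKQN]M[SA][SAG]X[WF][SAG];
  * segment 39-74 has an average mass of ~3.8 kDa;
  * a generic globular stand-in for the annexin core follows from ~191.

TDP-43-like chain (414 residues)
  * glycine-rich region G284-G310, hydrophobic region M311-S342 and a
    Q/N-rich region from Q343, mirroring the organization of the TDP-43
    C-terminal low-complexity domain;
  * named residues fixed: G282/G283/G284, F289, R293, G310, M311, A326,
    Q327, W334, S342, Q343, N345, N352, G357, Q360, S409, S410;
  * segment 284-345 has an average mass of ~6.2 kDa (282-345: ~6.3 kDa).

Use these for tests, demos and seeded simulations; analyses of the real
proteins require the corresponding UniProt sequences.
"""

from .proteome import SequenceRecord

#: density-derived 11-residue motif for the short filament chain
FILAMENT_MOTIF = "G[NMQ]X[SA][EDRKQN]M[SA][SAG]X[WF][SAG]"

SYNTHETIC_ANXA11_LIKE = SequenceRecord(
    identifier="SYN_ANXA11_LIKE",
    description="SYN_ANXA11_LIKE synthetic ANXA11-like chain (not UniProt P50995)",
    residues=(
        "MSYPGYPPSGQYPPAQSYGPGPSASAPGYSPPSQGGISLGQFATQGNQNMQSFLSGNSSN"
        "MSATWGGANMPTTYASGSYGPQQASSSAPQAYSGPPSQPPASPQGPSYQSASSPPSPSAQ"
        "PGGQYPAGSGSQPSSGQAGPGGAQGQQGYPAPAQPSSPSPPPQAYPGQQGYYYGPPSAAA"
        "YPGSSPSGSGDLLYPDLQDKDRRMPVEHGFATFEKLWATNRCWVNPVAGESEFPSAVARN"
        "IPPKSITNATITHNPYRYARWVTILSFNRWVRYLNMKNTATGEKFQTAYKKDLEIEKKQA"
        "LQGGDPNITIIWRELDNLWATTFEVGKVNEYYHAVNQDAWYAFNHRLPAWLTWNDDIGII"
        "LHSSSVTIEQFIWTAHTNNVKTQAPAIFTYPYRIVITDTNILFKLTTTKTRNIRIFRCKF"
        "TSTFLWNLYCVAFGWPGFRKDYKQNQCERNKYTPEGIYQQRYNGRYRRWPRVIWPILTTV"
        "EIALEWSYEMSVLLKYLTMRQTVRK"
    ),
)

SYNTHETIC_TDP43_LIKE = SequenceRecord(
    identifier="SYN_TDP43_LIKE",
    description="SYN_TDP43_LIKE synthetic TDP-43-like chain (not UniProt Q13148)",
    residues=(
        "AASRKQPNLQEAKPRWSTRVKTVTFFTRFHSEMASLNGQLPYCEEGDPIAIESLWSVNAK"
        "EHEVTVAKAEAINMTFNESLAATKDLKLKALEVNVPRKKKTKGLRRRMEIGLSAKYNMKE"
        "AKETVLTSDLMEFLPRVVMAYILESTGQYRSVEILQAAEDTLPNSAVALPQHKMVCDAAN"
        "ILIGTMLPLQDYESVVSAKGKSTETTKQYHLKFSREGKGESRILDFDSFYVDACTMLITP"
        "NSDRFKVDLQLGELNSLRNPMLFSRATVLNRDTTKLLDLSDGGGGSNGFGASRGANGNNG"
        "NNNGNNGSSGMIIFSFLAAFAMLASAQIMMAMAWLLLALSSSQNNQNQQNNNQQNQGNQQ"
        "QQSSAGQGFGMSAQFSMNGASAMMMAMSNSAASNGMNNFGFQSNAFSASSGSNM"
    ),
)

#: published boundaries of the ordered filament fold (1-based, inclusive)
ANXA11_FOLD_RANGE = (39, 74)
TDP43_FOLD_RANGE = (284, 345)
TDP43_FOLD_RANGE_ALT = (282, 345)

#: interface segments: S55-Y74 of the ANXA11 chain, Q327-N345 of the TDP-43 chain
ANXA11_INTERFACE_RANGE = (55, 74)
TDP43_INTERFACE_RANGE = (327, 345)
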