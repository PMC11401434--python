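"""Packaged synthetic exemplar sequences for the generator and builtin profiles.

All sequences here are synthetic (drawn from a fixed pseudo-random construction),
not real database entries.  FN3/FReD exemplars use a cysteine-free alphabet so
they can never collide with the tenascin-type EGF cysteine grammar.  The four
FReD templates descend from one synthetic ancestor with 25% of positions
substituted per paralog (pairwise identity ~55-65%), mimicking the divergence
regime of real tenascin fibrinogen-related domains.
"""

#: ~90-residue FN3-like exemplars (beta-sandwich length class).
FN3_EXEMPLARS = [
    "VPNFTEVMHIVMYNFWPFYYANMDGEKDSFGMRWWNIKDWIHALLRAEQQRGNWQWLYFHSFEPQAYMQMVDTADNQYPDMSPVNVGDYL",
    "GPDDGWHYPKIHSRHAREYFSRMTSSPDSWFFIRWDAWFLWVTMVSNNIATIWWILMYLTYNYIPLERNTRMQYEAWSIQNNIIWQFPKD",
]

#: ~230-residue FReD templates keyed by tenascin paralog label.
FRED_TEMPLATES = {
    "TNC": "YQATAMHQWGLGTRVGVPPWFIEAGFALKTSSSGGMAHGRAINYSWIWPRSIVVHQIYVVSYVGQTDAGAIHGHQNVRKWTMHEYWERWKVFMLAINYMKSRQGVTLDTMSSFHNMKWDTVVIKKEDFGGYDPNRWNEHQSLNVFDFVDHRNFFFYQQSVKEYSQATRFARVGFQNMLTNKELRHYTSLYSHVEWFLQWFDLRQWRIKQAAPSAPWRLKPMIREDWFTDV",
    "TNR": "QQWTVMHQFGLLTPHDAPPDSIEHGIDMFTKGPGGSAAGRAINYSSIMPAWIVVMRMSVVSYVGQKDAGMDHIHQSLRKWTMLEKHEKWKMFDVAMNDMKSDQHVTPETMWLFTGMVWKDVVIKKENFGGYDRNMNNEHELFNVFDDVDSFTFFFMQRSTKEALHDKRFDGVEHFRMLTEEDLRVYGQMSSIYNWFLIWYELRRWRDKQAVADAPGRSKPMIEEWFFTEV",
    "TNW": "YMATQMGQFGLWTTHWVPMDSFEAGIAMKTKKSERSAHGDADNMSWIWPAWVVYQQMYTVSVFGQLDAGTIVGHNPLRLETDDEYWERWKKFMVAMIYTKSRQLETPETMSPFHGMVWDGVVIKPEYWGTYDRNMFSEWQGLNVFDDWDHHMFDFYQHSTMEYLTDKRFDGVGFFMMLTNEDLRHYGSLYFHYMWDAQWYDLRQWYGKQAVAGAWWRESPDNMEWFFTLD",
    "TNX": "YQATAMAQFGLWTKFYVPPDPIEQGIPHKYKKSDGSAKGRLINYSWFWPAWIVVQGMYLVSYVGQLDRLAIHIHQSWRGWPMHPYWERWKVFMVHMKYMKSRISKMPEIMTLTEGMSWDGQVIKKENLGIGDPNMWSEHQQLIDFDDVDHRTWFFYQYSTKHYLHDKRFDGVYFLMMTTNEDLRHYGIMYSHYRWFLHWYDLRQWRDKQRFALAPWRSRPMIMEWFSQGV",
}

#: 16-residue signal peptide template (Met + hydrophobic core).
SIGNAL_TEMPLATE = "MALLLVLALLAVQGSA"

#: 144-residue assembly-domain template appended directly after the signal.
#: With the 16-residue signal it puts cysteines at absolute positions
#: 64, 111, 113, 140, 146, 147 (the numbering convention of human TNC),
#: the conserved motif VFNHVYNINVP at 70..80, and a heptad-repeat window at
#: 116..136 whose central residues spell RLEALE (an RhExLE instance).
ASSEMBLY_TEMPLATE = "STHMHMYAGMVMADYPHFHLFHFMWKTEPTPFSMFAQIGHHIIHKTYCGPMDKVFNHVYNINVPSFYGVKFYHEDYVAYKFEVPQLHNEAWRRACFCAILEELRLEALELEEELEELEEEFYLCISWDWCCAEASHTFYMRYDG"

#: Absolute (1-based, full-protein) cysteine reference positions.
ASSEMBLY_CYS_POSITIONS = (64, 111, 113, 140, 146, 147)

#: Relative 1-based spans inside ASSEMBLY_TEMPLATE that must not be mutated
#: by the generator (cysteines, conserved motif, heptad window).
ASSEMBLY_CONSTRAINED = sorted(
    set([48, 95, 97, 124, 130, 131])
    | set(range(54, 54 + 11))
    | set(range(100, 100 + 21))
)

#: Short degenerate assembly region used for synthetic TNX (single cysteine,
#: no heptad) mirroring the short TNX assembly domains of tetrapods.
TNX_ASSEMBLY_TEMPLATE = "QPSTNQSGTPSLDQCGQSTNPDSGQTNSDQ"
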