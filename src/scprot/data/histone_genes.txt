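# Default human histone gene symbols (HGNC, current cluster nomenclature
# plus the legacy HIST* aliases). One symbol per line; '#' starts a comment.
# Linker histone H1
H1-0
H1-1
H1-2
H1-3
H1-4
H1-5
H1-6
H1-7
H1-8
H1-10
# Core histone H2A
H2AC1
H2AC4
H2AC6
H2AC11
H2AC12
H2AC13
H2AC14
H2AC15
H2AC16
H2AC17
H2AC18
H2AC19
H2AC20
H2AC21
H2AZ1
H2AZ2
H2AX
H2AJ
MACROH2A1
MACROH2A2
# Core histone H2B
H2BC1
H2BC3
H2BC4
H2BC5
H2BC6
H2BC7
H2BC8
H2BC9
H2BC10
H2BC11
H2BC12
H2BC13
H2BC14
H2BC15
H2BC17
H2BC18
H2BC21
# Core histone H3
H3C1
H3C2
H3C3
H3C4
H3C6
H3C7
H3C8
H3C10
H3C11
H3C12
H3C13
H3C14
H3C15
H3-3A
H3-3B
H3-4
H3-5
# Core histone H4
H4C1
H4C2
H4C3
H4C4
H4C5
H4C6
H4C8
H4C9
H4C11
H4C12
H4C13
H4C14
H4C15
H4-16
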