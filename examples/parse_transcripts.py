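"""Parse a CHAT transcript and list the child's word types.

Builds a tiny two-speaker CHAT document in memory, parses it for the target
child (speaker code CHI), and prints the session age and word types.  Only
the child's main tiers count; the mother's words, dependent tiers and CLAN
annotation codes are excluded by the tokenizer rules.
"""

from aoacorpus import parse_chat

DOC = """\
@UTF8
@Begin
@Participants:\tCHI Anne Target_Child , MOT Gail Mother
@ID:\teng|demo|CHI|2;3.10|female|||Target_Child|||
@ID:\teng|demo|MOT|||||Mother|||
*CHI:\tball .
*MOT:\tthat's the red ball .
*CHI:\txxx &-um doggy [!] .
*CHI:\tchoo+choo more@c .
@End
"""

session = parse_chat(DOC, target_speaker="CHI")
print(f"child age: {session.child_age_months} months")
print(f"word types: {sorted(session.child_word_types)}")
# The age is 2 years + 3 months + 10/30.44 months = 27.33.  The word list
# keeps 'ball', 'doggy', the compound 'choo+choo' and the stem of the child
# form 'more@c'; 'xxx' (unintelligible), '&-um' (filler), '[!]' (code) and
# everything the mother said are dropped.
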