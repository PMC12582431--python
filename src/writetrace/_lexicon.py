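"""Minimal closed-class (function word) inventories for English and Spanish.

These lists cover determiners, pronouns, prepositions, conjunctions,
auxiliaries and common particles.  They are deliberately small: the
open/closed ratio is robust to inventory size for the synthetic and essay
texts this package targets, and callers can supply their own lexicon.
"""

ENGLISH_CLOSED_CLASS = frozenset(
    """
    a an the this that these those some any each every no
    i you he she it we they me him her us them my your his its our their
    mine yours hers ours theirs myself yourself himself herself itself
    ourselves themselves who whom whose which what
    in on at by for from to of with without about against between among
    through during before after above below under over up down out off
    into onto upon near
    and or but nor so yet if because although though while whereas unless
    until when where why how than as
    is am are was were be been being have has had do does did will would
    shall should may might must can could
    not n't there here then also just only very too quite rather
    """.split()
)

SPANISH_CLOSED_CLASS = frozenset(
    """
    el la los las un una unos unas este esta estos estas ese esa esos esas
    aquel aquella aquellos aquellas algun alguna algunos algunas ningun
    ninguna cada todo toda todos todas
    yo tu usted el ella nosotros nosotras vosotros vosotras ellos ellas
    me te se nos os lo le les mi mis tus su sus nuestro nuestra nuestros
    nuestras vuestro vuestra
    en de a por para con sin sobre contra entre desde hasta hacia segun
    tras durante ante bajo
    y e o u pero sino aunque porque pues si cuando donde como que cual
    quien cuyo mientras
    es son era eran fue fueron ser estar esta estan estaba estaban hay
    haber ha han habia tener tiene tienen puede pueden debe deben
    no ni ya muy mas menos tambien tampoco solo asi
    """.split()
)

CLOSED_CLASS = {"L1": ENGLISH_CLOSED_CLASS, "L2": SPANISH_CLOSED_CLASS}
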