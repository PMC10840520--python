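species	barcoded
Diplatys flavicollis	true
Paradiplatys gladiator	false
Challia imamurai	true
Echinosoma akitai	false
Parapsalis infernalis	true
Isolabis ishigakiensis	false
Anisolabella marginalis	true
Anisolabella ryukyuensis	true
Anisolabis boninensis	false
Anisolabis maritima	true
Anisolabis picea	false
Anisolabis seirokui	true
Gonolabis distincta	true
Gonolabis michikoae	true
Gonolabis miyatakei	true
Euborellia annulata	true
Euborellia annulipes	true
Euborellia pallipes	true
Euborellia plebeja	true
Labidura riparia	true
Nala lividipes	true
Chaetospania hexagonalis	true
Labia minor	true
Paralabellula curvicauda	true
Spongovostox sakaii	true
Marava arachidis	true
Nesogaster lewisi	true
Proreus simulans	true
Eparchus yezoensis	true
Timomenus komarowi	false
Paratimomenus flavocapitatus	false
Anechura harmandi	true
Anechura japonica	false
Elaunon bipartitus	true
Forficula auricularia	true
Forficula hiromasai	true
Forficula mikado	true
Forficula paratomis	false
Forficula planicollis	false
Forficula scudderii	false
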