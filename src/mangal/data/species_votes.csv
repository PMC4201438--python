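species,pct_yes
Avicennia alba,100
Avicennia marina,100
Bruguiera gymnorrhiza,100
Bruguiera parviflora,100
Bruguiera sexangula,100
Ceriops decandra,100
Ceriops tagal,100
Rhizophora apiculata,100
Rhizophora mucronata,100
Rhizophora stylosa,100
Sonneratia alba,100
Sonneratia apetala,100
Sonneratia caseolaris,100
Sonneratia griffithii,100
Xylocarpus granatum,100
Xylocarpus moluccensis,100
Avicennia bicolor,92
Avicennia germinans,92
Avicennia officinalis,92
Bruguiera cylindrica,92
Bruguiera hainesii,92
Ceriops australis,92
Rhizophora mangle,92
Rhizophora racemosa,92
Rhizophora samoensis,92
Sonneratia ovata,92
Xylocarpus mekongensis,92
Avicennia integra,85
Avicennia schaueriana,85
Bruguiera exaristata,85
Heritiera littoralis,85
Kandelia candel,85
Lumnitzera littorea,85
Sonneratia lanceolata,85
Lumnitzera racemosa,80
Avicennia lanata,77
Avicennia rumphiana,77
Ceriops zipelliana,77
Excoecaria agallocha,77
Excoecaria indica,77
Heritiera fomes,77
Aegialitis rotundifolia,69
Aegiceras corniculatum,69
Aegiceras floridum,69
Heritiera globosa,69
Kandelia obovata,69
Laguncularia racemosa,69
Lumnitzera rosea,69
Aegialitis annulata,62
Nypa fruticans,54
Pelliciera rhizophoreae,54
Pemphis acidula,54
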