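<?xml version='1.0' encoding='UTF-8'?>
<pnml xmlns="http://www.pnml.org/version-2009/grammar/pnml">
  <net id="fig5" type="http://www.pnml.org/version-2009/grammar/ptnet">
    <page id="page0">
      <place id="p1"/>
      <place id="p2"/>
      <transition id="t1"/>
      <transition id="t2"/>
      <transition id="t3"/>
      <transition id="t4"/>
      <transition id="t5"/>
      <arc id="a0" source="p1" target="t2"/>
      <arc id="a1" source="p1" target="t4"/>
      <arc id="a2" source="p2" target="t3"/>
      <arc id="a3" source="p2" target="t5"/>
      <arc id="a4" source="t1" target="p1"/>
      <arc id="a5" source="t1" target="p2"/>
      <arc id="a6" source="t2" target="p2"/>
      <arc id="a7" source="t3" target="p1"/>
    </page>
  </net>
</pnml>
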