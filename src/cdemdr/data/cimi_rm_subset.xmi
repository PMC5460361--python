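<?xml version="1.0" encoding="UTF-8"?>
<!-- Hand-built synthetic XMI rendering of the core ITEM/ITEM_GROUP/ELEMENT
     pattern of a CIMI-style clinical reference model, in the artifact's
     documented minimal XMI dialect.  This is a reconstruction for testing,
     not the published v2.0.1 model file. -->
<xmi:XMI xmi:version="2.1"
         xmlns:xmi="http://www.omg.org/XMI"
         xmlns:uml="http://www.omg.org/spec/UML">
  <uml:Model name="CIMI_RM_subset">
    <packagedElement xmi:type="uml:Package" name="Primitive Types">
      <packagedElement xmi:type="uml:PrimitiveType" xmi:id="p-string" name="String"/>
      <packagedElement xmi:type="uml:PrimitiveType" xmi:id="p-real" name="Real"/>
      <packagedElement xmi:type="uml:PrimitiveType" xmi:id="p-integer" name="Integer"/>
      <packagedElement xmi:type="uml:PrimitiveType" xmi:id="p-boolean" name="Boolean"/>
    </packagedElement>
    <packagedElement xmi:type="uml:Package" name="CIMI Core Model">
      <packagedElement xmi:type="uml:Class" xmi:id="c-locatable" name="LOCATABLE" isAbstract="true">
        <ownedAttribute name="archetype_node_id" type="p-string" lower="1" upper="1"/>
      </packagedElement>
      <packagedElement xmi:type="uml:Class" xmi:id="c-item" name="ITEM" isAbstract="true">
        <generalization general="c-locatable"/>
        <ownedAttribute name="name" type="p-string" lower="1" upper="1"/>
      </packagedElement>
      <packagedElement xmi:type="uml:Class" xmi:id="c-item-group" name="ITEM_GROUP">
        <generalization general="c-item"/>
      </packagedElement>
      <packagedElement xmi:type="uml:Class" xmi:id="c-element" name="ELEMENT">
        <generalization general="c-item"/>
        <ownedAttribute name="value" type="c-data-value" lower="0" upper="1"/>
      </packagedElement>
      <packagedElement xmi:type="uml:Association" xmi:id="a-item" name="ItemGroupItems">
        <ownedEnd name="item" type="c-item" lower="0" upper="*"/>
        <ownedEnd type="c-item-group" lower="0" upper="1"/>
      </packagedElement>
    </packagedElement>
    <packagedElement xmi:type="uml:Package" name="Data Value Types">
      <packagedElement xmi:type="uml:Class" xmi:id="c-data-value" name="DATA_VALUE" isAbstract="true"/>
      <packagedElement xmi:type="uml:Class" xmi:id="c-text" name="TEXT">
        <generalization general="c-data-value"/>
        <ownedAttribute name="value" type="p-string" lower="1" upper="1"/>
      </packagedElement>
      <packagedElement xmi:type="uml:Class" xmi:id="c-coded-text" name="CODED_TEXT">
        <generalization general="c-text"/>
        <ownedAttribute name="code" type="p-string" lower="1" upper="1"/>
        <ownedAttribute name="terminology_id" type="p-string" lower="1" upper="1"/>
      </packagedElement>
      <packagedElement xmi:type="uml:Class" xmi:id="c-quantity" name="QUANTITY">
        <generalization general="c-data-value"/>
        <ownedAttribute name="magnitude" type="p-real" lower="1" upper="1"/>
        <ownedAttribute name="units" type="p-string" lower="0" upper="1"/>
      </packagedElement>
    </packagedElement>
    <packagedElement xmi:type="uml:Package" name="Party">
      <packagedElement xmi:type="uml:Class" xmi:id="c-party" name="PARTY">
        <ownedAttribute name="name" type="c-text" lower="1" upper="1"/>
      </packagedElement>
      <packagedElement xmi:type="uml:Class" xmi:id="c-role" name="ROLE">
        <ownedAttribute name="role_type" type="c-coded-text" lower="0" upper="1"/>
      </packagedElement>
      <packagedElement xmi:type="uml:Association" xmi:id="a-role" name="PartyRoles">
        <ownedEnd name="roles" type="c-role" lower="0" upper="*"/>
        <ownedEnd type="c-party" lower="1" upper="1"/>
      </packagedElement>
    </packagedElement>
  </uml:Model>
</xmi:XMI>
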